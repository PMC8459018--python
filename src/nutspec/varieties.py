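"""Published walnut composition reference values.

Per-variety means and standard errors of total fat (% by weight) and of the
16 fatty acids routinely resolved by GC-FID in walnut oil (relative % of
total fatty acids), for five commercial *Juglans regia* varieties grown in
the Alentejo region. These values parameterize the synthetic-data generator
and the composition bookkeeping, and define the fixed family memberships
(4 SFA, 8 MUFA, 4 PUFA).

Acid names use a plain-ASCII convention: ``C18:1w9c`` stands for the cis
Δ9 18:1 (oleic acid), ``w`` replacing ω.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SFA_ACIDS: tuple[str, ...] = ("C16:0", "C17:0", "C18:0", "C21:0")
MUFA_ACIDS: tuple[str, ...] = (
    "C16:1w7c",
    "C16:1w9c",
    "C17:1w7c",
    "C17:1w9c",
    "C18:1w9t",
    "C18:1w9c",
    "C18:1w7c",
    "C20:1w9",
)
PUFA_ACIDS: tuple[str, ...] = ("C18:2w6ct", "C18:2w6c", "C18:3w6", "C18:3w3")
ALL_ACIDS: tuple[str, ...] = SFA_ACIDS + MUFA_ACIDS + PUFA_ACIDS

#: fixed family membership of the 16 acids
FAMILIES: dict[str, tuple[str, ...]] = {
    "SFA": SFA_ACIDS,
    "MUFA": MUFA_ACIDS,
    "PUFA": PUFA_ACIDS,
}

#: trivial / common names of the acids most discussed in the literature
COMMON_NAMES: dict[str, str] = {
    "C16:0": "palmitic",
    "C17:0": "margaric",
    "C18:0": "stearic",
    "C21:0": "heneicosanoic",
    "C16:1w7c": "palmitoleic",
    "C16:1w9c": "hypogeic",
    "C17:1w7c": "cis-10-heptadecenoic",
    "C17:1w9c": "civetic",
    "C18:1w9t": "elaidic",
    "C18:1w9c": "oleic",
    "C18:1w7c": "vaccenic",
    "C20:1w9": "gondoic",
    "C18:2w6ct": "linolelaidic",
    "C18:2w6c": "linoleic",
    "C18:3w6": "gamma-linolenic",
    "C18:3w3": "alpha-linolenic",
}


@dataclass(frozen=True)
class VarietyProfile:
    """Composition profile of one variety: means and SEs of total fat and acids."""

    name: str
    mean_total_fat: float
    se_total_fat: float
    fa_means: dict[str, float] = field(default_factory=dict)
    fa_ses: dict[str, float] = field(default_factory=dict)
    #: reported family totals (measured on unrounded data, so they can differ
    #: from sums of the rounded member means in the last digit)
    family_means: dict[str, float] = field(default_factory=dict)
    family_ses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [a for a in ALL_ACIDS if a not in self.fa_means]
        if missing:
            raise ValueError(f"{self.name}: missing acid means for {missing}")
        if any(v < 0 for v in self.fa_means.values()) or self.mean_total_fat < 0:
            raise ValueError(f"{self.name}: negative composition mean")
        if any(v < 0 for v in self.fa_ses.values()) or self.se_total_fat < 0:
            raise ValueError(f"{self.name}: negative SE")
        total = sum(self.fa_means[a] for a in ALL_ACIDS)
        if not 95.0 <= total <= 105.0:
            raise ValueError(
                f"{self.name}: acid means sum to {total:.2f}, outside [95, 105]"
            )

    def family_mean(self, family: str) -> float:
        return sum(self.fa_means[a] for a in FAMILIES[family])


_FAMILY_TOTALS = {
    # variety: {family: (mean, SE)}
    "Chandler": {"SFA": (8.87, 0.13), "MUFA": (14.44, 0.38), "PUFA": (76.69, 0.42)},
    "Franquette": {"SFA": (10.17, 0.32), "MUFA": (16.79, 0.51), "PUFA": (73.03, 0.56)},
    "Howard": {"SFA": (8.73, 0.37), "MUFA": (13.78, 1.00), "PUFA": (77.48, 1.36)},
    "Lara": {"SFA": (9.78, 0.13), "MUFA": (13.62, 0.34), "PUFA": (76.60, 0.39)},
    "Tulare": {"SFA": (9.44, 0.24), "MUFA": (13.54, 0.48), "PUFA": (77.02, 0.63)},
}


def _profile(name, fat, acids):
    means = {a: m for a, (m, _) in acids.items()}
    ses = {a: s for a, (_, s) in acids.items()}
    fam = _FAMILY_TOTALS[name]
    return VarietyProfile(
        name, fat[0], fat[1], means, ses,
        {f: m for f, (m, _) in fam.items()}, {f: s for f, (_, s) in fam.items()},
    )


#: per-variety (mean, SE) chemistry: total fat % by weight, acids as relative %
WALNUT_PROFILES: tuple[VarietyProfile, ...] = (
    _profile(
        "Chandler",
        (65.58, 0.91),
        {
            "C16:0": (5.96, 0.10),
            "C17:0": (0.05, 0.00),
            "C18:0": (2.28, 0.08),
            "C21:0": (0.57, 0.11),
            "C16:1w7c": (0.05, 0.00),
            "C16:1w9c": (0.06, 0.00),
            "C17:1w7c": (0.02, 0.00),
            "C17:1w9c": (0.03, 0.00),
            "C18:1w9t": (0.06, 0.00),
            "C18:1w9c": (12.98, 0.41),
            "C18:1w7c": (1.08, 0.09),
            "C20:1w9": (0.14, 0.02),
            "C18:2w6ct": (0.07, 0.01),
            "C18:2w6c": (62.22, 0.51),
            "C18:3w6": (0.17, 0.04),
            "C18:3w3": (14.23, 0.45),
        },
    ),
    _profile(
        "Franquette",
        (68.86, 0.68),
        {
            "C16:0": (7.17, 0.27),
            "C17:0": (0.06, 0.02),
            "C18:0": (2.40, 0.09),
            "C21:0": (0.54, 0.30),
            "C16:1w7c": (0.07, 0.02),
            "C16:1w9c": (0.16, 0.05),
            "C17:1w7c": (0.02, 0.01),
            "C17:1w9c": (0.03, 0.00),
            "C18:1w9t": (0.06, 0.01),
            "C18:1w9c": (14.84, 0.63),
            "C18:1w7c": (1.47, 0.27),
            "C20:1w9": (0.14, 0.05),
            "C18:2w6ct": (0.09, 0.03),
            "C18:2w6c": (58.64, 0.78),
            "C18:3w6": (0.18, 0.12),
            "C18:3w3": (14.12, 0.64),
        },
    ),
    _profile(
        "Howard",
        (68.78, 2.24),
        {
            "C16:0": (5.88, 0.30),
            "C17:0": (0.05, 0.00),
            "C18:0": (2.25, 0.20),
            "C21:0": (0.56, 0.28),
            "C16:1w7c": (0.05, 0.00),
            "C16:1w9c": (0.06, 0.01),
            "C17:1w7c": (0.04, 0.02),
            "C17:1w9c": (0.03, 0.00),
            "C18:1w9t": (0.06, 0.01),
            "C18:1w9c": (12.43, 0.90),
            "C18:1w7c": (0.99, 0.09),
            "C20:1w9": (0.12, 0.03),
            "C18:2w6ct": (0.06, 0.00),
            "C18:2w6c": (60.36, 0.74),
            "C18:3w6": (0.14, 0.07),
            "C18:3w3": (16.92, 1.25),
        },
    ),
    _profile(
        "Lara",
        (66.91, 0.69),
        {
            "C16:0": (6.76, 0.12),
            "C17:0": (0.06, 0.00),
            "C18:0": (2.38, 0.07),
            "C21:0": (0.58, 0.15),
            "C16:1w7c": (0.06, 0.01),
            "C16:1w9c": (0.09, 0.02),
            "C17:1w7c": (0.03, 0.01),
            "C17:1w9c": (0.03, 0.00),
            "C18:1w9t": (0.05, 0.00),
            "C18:1w9c": (12.16, 0.37),
            "C18:1w7c": (1.01, 0.09),
            "C20:1w9": (0.17, 0.03),
            "C18:2w6ct": (0.07, 0.01),
            "C18:2w6c": (63.74, 0.58),
            "C18:3w6": (0.18, 0.05),
            "C18:3w3": (12.61, 0.45),
        },
    ),
    _profile(
        "Tulare",
        (66.29, 0.95),
        {
            "C16:0": (6.65, 0.18),
            "C17:0": (0.06, 0.00),
            "C18:0": (2.47, 0.11),
            "C21:0": (0.26, 0.02),
            "C16:1w7c": (0.06, 0.00),
            "C16:1w9c": (0.07, 0.00),
            "C17:1w7c": (0.02, 0.00),
            "C17:1w9c": (0.03, 0.00),
            "C18:1w9t": (0.05, 0.00),
            "C18:1w9c": (12.27, 0.48),
            "C18:1w7c": (0.93, 0.02),
            "C20:1w9": (0.10, 0.01),
            "C18:2w6ct": (0.06, 0.00),
            "C18:2w6c": (62.27, 0.76),
            "C18:3w6": (0.09, 0.02),
            "C18:3w3": (14.60, 0.70),
        },
    ),
)

#: kernels imaged per variety after discarding visually defective nuts
IMAGED_KERNEL_COUNTS: dict[str, int] = {
    "Chandler": 31,
    "Franquette": 29,
    "Howard": 32,
    "Lara": 35,
    "Tulare": 38,
}

#: pretreatment codes swept when calibrating each analyte (the distinct codes
#: in routine WinISI-style use: scatter correction x gap-segment derivative)
PRETREATMENT_SWEEP: tuple[str, ...] = (
    "None 0,0,1,1",
    "SNV 0,0,1,1",
    "SNV 1,5,5,1",
    "SNV 2,5,5,1",
    "SNV 2,10,10,1",
    "MSC 0,0,1,1",
    "MSC 1,5,5,1",
    "MSC 2,5,5,1",
    "MSC 2,10,10,1",
    "Detrend 2,10,10,1",
    "SNV+detrend 2,5,5,1",
)
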