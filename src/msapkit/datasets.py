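"""Bundled example data: MSAP counts from a salt-stress survey of rice.

Band-type and transition-pattern counts scored from MSAP gels of four rice
genotypes (IR29, Nipponbare, Pokkali, Geumgangbyeo), shoot and root at the
seedling stage, under control and 24 h of 150 mM NaCl. Roughly 1600 clear,
reproducible fragments were scored per genotype/tissue/condition across 32
primer combinations.

These are the summary counts only — per-locus gel scores were never
deposited — so they exercise the summary statistics and contingency tests,
while per-locus workflows use :mod:`msapkit.simulate`.
"""

from __future__ import annotations

from .msap_core import BandTypeCounts

__all__ = [
    "GENOTYPES",
    "TISSUES",
    "CONDITIONS",
    "band_type_counts",
    "pattern_class_counts",
]

GENOTYPES = ("IR29", "Nipponbare", "Pokkali", "Geumgangbyeo")
TISSUES = ("shoot", "root")
CONDITIONS = ("control", "salinity")

# (genotype, tissue, condition) -> (n_I, n_II, n_III, n_IV)
_BAND_TYPE_COUNTS: dict[tuple[str, str, str], tuple[int, int, int, int]] = {
    ("IR29", "shoot", "control"): (665, 201, 322, 446),
    ("IR29", "shoot", "salinity"): (789, 113, 425, 308),
    ("Nipponbare", "shoot", "control"): (877, 246, 205, 306),
    ("Nipponbare", "shoot", "salinity"): (692, 290, 235, 418),
    ("Pokkali", "shoot", "control"): (698, 293, 171, 471),
    ("Pokkali", "shoot", "salinity"): (566, 317, 158, 593),
    ("Geumgangbyeo", "shoot", "control"): (838, 143, 160, 489),
    ("Geumgangbyeo", "shoot", "salinity"): (1067, 119, 93, 350),
    ("IR29", "root", "control"): (1276, 7, 98, 254),
    ("IR29", "root", "salinity"): (1314, 23, 84, 211),
    ("Nipponbare", "root", "control"): (1103, 34, 239, 259),
    ("Nipponbare", "root", "salinity"): (1310, 39, 83, 203),
    ("Pokkali", "root", "control"): (1231, 32, 91, 232),
    ("Pokkali", "root", "salinity"): (1232, 34, 114, 202),
    ("Geumgangbyeo", "root", "control"): (1311, 10, 95, 218),
    ("Geumgangbyeo", "root", "salinity"): (1319, 19, 97, 197),
}

# (genotype, tissue) -> counts of the 16 control->stress pattern classes A-P.
_PATTERN_CLASS_COUNTS: dict[tuple[str, str], dict[str, int]] = {
    ("IR29", "shoot"): dict(A=20, B=108, C=505, D=184, E=62, F=136, G=85,
                            H=25, I=50, J=127, K=18, L=113, M=29, N=77, O=42, P=53),
    ("Nipponbare", "shoot"): dict(A=62, B=44, C=541, D=180, E=70, F=53, G=27,
                                  H=37, I=49, J=50, K=142, L=98, M=96, N=43, O=71, P=71),
    ("Pokkali", "shoot"): dict(A=42, B=30, C=287, D=373, E=17, F=42, G=19,
                               H=30, I=43, J=36, K=202, L=75, M=134, N=17, O=217, P=68),
    ("Geumgangbyeo", "shoot"): dict(A=17, B=12, C=775, D=282, E=80, F=105, G=107,
                                    H=16, I=56, J=44, K=30, L=16, M=17, N=21, O=24, P=27),
    ("IR29", "root"): dict(A=3, B=54, C=1238, D=188, E=3, F=39, G=34,
                           H=3, I=10, J=22, K=7, L=7, M=21, N=1, O=0, P=2),
    ("Nipponbare", "root"): dict(A=7, B=55, C=1168, D=131, E=17, F=26, G=49,
                                 H=7, I=13, J=16, K=12, L=7, M=46, N=5, O=5, P=21),
    ("Pokkali", "root"): dict(A=4, B=54, C=1131, D=153, E=21, F=28, G=52,
                              H=3, I=5, J=22, K=22, L=38, M=37, N=0, O=7, P=5),
    ("Geumgangbyeo", "root"): dict(A=3, B=51, C=1240, D=153, E=5, F=30, G=43,
                                   H=4, I=5, J=17, K=7, L=29, M=32, N=0, O=2, P=10),
}


def band_type_counts(genotype: str, tissue: str, condition: str) -> BandTypeCounts:
    """Band-type counts I-IV for one genotype/tissue/condition."""
    key = (genotype, tissue, condition)
    if key not in _BAND_TYPE_COUNTS:
        raise KeyError(
            f"no counts for {key}; genotypes {GENOTYPES}, tissues {TISSUES}, "
            f"conditions {CONDITIONS}")
    return BandTypeCounts(*_BAND_TYPE_COUNTS[key])


def pattern_class_counts(genotype: str, tissue: str) -> dict[str, int]:
    """Counts of the 16 control-to-stress pattern classes A-P."""
    key = (genotype, tissue)
    if key not in _PATTERN_CLASS_COUNTS:
        raise KeyError(f"no pattern counts for {key}")
    return dict(_PATTERN_CLASS_COUNTS[key])
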