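"""Published selection statistics from the original phantom measurement study.

The measurement data themselves were never deposited, but the study's printed
per-method ANOVA statistics (Analysis 1) and per-feature F-values
(Analysis 2) are reproduced here verbatim.  They serve as worked-example
inputs for :func:`msfs.selection.select_top`: applying the selection rule
(p < 0.05, highest F) to these tables must recover the study's published
choices — five normalization methods and the ten rank-ordered features.

In the per-feature table, ``None`` marks a feature printed as statistically
insignificant (p >= 0.05) for that normalization method.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from .selection import AnovaResult, SelectionReport, select_top

#: Analysis 1 — (p, F) per normalization method over the [6750 x 10] matrices.
METHOD_STATS: Dict[str, Tuple[float, float]] = {
    "DS": (0.023971, 1.07541),
    "ZS": (0.022969, 1.075852),
    "LS": (1.0, 0.59923),
    "MM": (1.0, 0.608231),
    "MSD": (0.049447, 1.062474),
    "RLSSV": (0.013245, 47.85685),
    "RLV": (0.494978, 1.00003),
    "RV": (0.029273, 1.071593),
    "FVC": (0.025485, 1.074304),
    "RSSV": (0.046762, 1.063453),
}

#: The five methods the study selected in Analysis 1.
SELECTED_METHODS = ("RLSSV", "DS", "ZS", "RV", "FVC")

#: Analysis 2 — F per (feature, method) over the five selected methods.
#: Column order as printed; None = insignificant (p >= 0.05), excluded.
FEATURE_METHOD_ORDER = ("ZS", "DS", "RLSSV", "RV", "FVC")
FEATURE_ROW_ORDER = ("SD", "M", "V", "S", "SE", "ICA", "SU", "PSD", "MAX", "MIN")
FEATURE_F: Dict[Tuple[str, str], Optional[float]] = {
    ("SD", "ZS"): None, ("SD", "DS"): 55.12, ("SD", "RLSSV"): 10.95,
    ("SD", "RV"): 103.64, ("SD", "FVC"): 160.47,
    ("M", "ZS"): None, ("M", "DS"): None, ("M", "RLSSV"): 5.46,
    ("M", "RV"): None, ("M", "FVC"): None,
    ("V", "ZS"): None, ("V", "DS"): 53.79, ("V", "RLSSV"): 13.76,
    ("V", "RV"): 88.70, ("V", "FVC"): 135.12,
    ("S", "ZS"): None, ("S", "DS"): None, ("S", "RLSSV"): 126.54,
    ("S", "RV"): None, ("S", "FVC"): None,
    ("SE", "ZS"): None, ("SE", "DS"): 70.59, ("SE", "RLSSV"): 9.48,
    ("SE", "RV"): 154.30, ("SE", "FVC"): 140.44,
    ("ICA", "ZS"): 8.48, ("ICA", "DS"): 2.36, ("ICA", "RLSSV"): None,
    ("ICA", "RV"): 10.22, ("ICA", "FVC"): None,
    ("SU", "ZS"): 282.76, ("SU", "DS"): 53.89, ("SU", "RLSSV"): 3.47,
    ("SU", "RV"): 88.70, ("SU", "FVC"): 48.21,
    ("PSD", "ZS"): 222.52, ("PSD", "DS"): None, ("PSD", "RLSSV"): None,
    ("PSD", "RV"): 11.59, ("PSD", "FVC"): 3.29,
    ("MAX", "ZS"): 6.76, ("MAX", "DS"): 4.26, ("MAX", "RLSSV"): None,
    ("MAX", "RV"): None, ("MAX", "FVC"): None,
    ("MIN", "ZS"): 4.45, ("MIN", "DS"): 37.55, ("MIN", "RLSSV"): None,
    ("MIN", "RV"): None, ("MIN", "FVC"): None,
}

#: The published rank order of the ten selected features (best first).
FEATURE_RANKING = (
    "SU-ZS", "PSD-ZS", "SD-FVC", "SE-RV", "SE-FVC",
    "V-FVC", "S-RLSSV", "SD-RV", "V-RV", "SU-RV",
)


def method_candidates() -> List[Tuple[str, AnovaResult]]:
    """Analysis-1 candidates built from the published (p, F) table."""
    return [
        (name, AnovaResult(F=F, p=p, df_between=5, df_within=6744))
        for name, (p, F) in METHOD_STATS.items()
    ]


def feature_candidates() -> List[Tuple[str, AnovaResult]]:
    """Analysis-2 candidates, method-major in printed order.

    Insignificant cells carry p = 1.0 (they fail the alpha filter), printed
    cells carry p = 0.0 (they passed it in the source table).
    """
    out = []
    for method in FEATURE_METHOD_ORDER:
        for feature in FEATURE_ROW_ORDER:
            F = FEATURE_F[(feature, method)]
            res = AnovaResult(
                F=0.0 if F is None else F,
                p=1.0 if F is None else 0.0,
                df_between=4,
                df_within=6745,
            )
            out.append((f"{feature}-{method}", res))
    return out


def select_published_methods(alpha: float = 0.05, k: int = 5) -> SelectionReport:
    return select_top(method_candidates(), alpha, k)


def select_published_features(alpha: float = 0.05, k: int = 10) -> SelectionReport:
    return select_top(feature_candidates(), alpha, k)
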