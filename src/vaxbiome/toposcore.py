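"""SIG1 / Grey / SIG2 classification of samples from configured species lists.

The harmful (SIG1) and beneficial (SIG2) species lists and both score
thresholds are user-supplied configuration.  The default S score,
n2 / (n1 + n2), is a documented stand-in: the pluggable
``score_function`` is the real contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .errors import ValidationError
from .io import AbundanceTable

CATEGORIES = ("SIG1", "Grey", "SIG2")


def default_score(n1: int, n2: int) -> float:
    """Stand-in S score: fraction of detected hits that are beneficial."""
    if n1 + n2 == 0:
        return float("nan")
    return n2 / (n1 + n2)


@dataclass
class SigConfig:
    sig1_species: list[str]
    sig2_species: list[str]
    detection_threshold: float = 0.0  # detected means abundance strictly above
    score_function: Callable[[int, int], float] = field(default=default_score)
    lower_threshold: float = 0.5
    upper_threshold: float = 0.79

    def __post_init__(self) -> None:
        if not self.sig1_species or not self.sig2_species:
            raise ValidationError("SIG1 and SIG2 species lists must be non-empty")
        overlap = set(self.sig1_species) & set(self.sig2_species)
        if overlap:
            raise ValidationError(f"SIG lists overlap: {sorted(overlap)[:5]}")
        if not 0 <= self.lower_threshold < self.upper_threshold <= 1:
            raise ValidationError("require 0 <= lower < upper <= 1")


@dataclass
class ToposcoreResult:
    sample_id: str
    n_sig1_detected: int
    n_sig2_detected: int
    s_score: float
    category: str  # SIG1 | Grey | SIG2 | undetermined


def count_sig_hits(profile: pd.Series, config: SigConfig) -> tuple[int, int]:
    """Counts of configured SIG1/SIG2 species detected above threshold."""
    def hits(species: list[str]) -> int:
        present = profile.reindex(species, fill_value=0.0)
        return int((present > config.detection_threshold).sum())

    return hits(config.sig1_species), hits(config.sig2_species)


def _categorize(s: float, config: SigConfig) -> str:
    if np.isnan(s):
        return "undetermined"
    if s < config.lower_threshold:
        return "SIG1"
    if s < config.upper_threshold:
        return "Grey"
    return "SIG2"


def compute_toposcore(profile: pd.Series, config: SigConfig,
                      sample_id: str = "") -> ToposcoreResult:
    n1, n2 = count_sig_hits(profile, config)
    s = config.score_function(n1, n2)
    return ToposcoreResult(sample_id=sample_id, n_sig1_detected=n1,
                           n_sig2_detected=n2, s_score=float(s),
                           category=_categorize(s, config))


def score_table(table: AbundanceTable, config: SigConfig) -> pd.DataFrame:
    rows = []
    for s in table.sample_ids:
        r = compute_toposcore(table.values.loc[s], config, sample_id=s)
        rows.append({"sample_id": r.sample_id, "n_sig1": r.n_sig1_detected,
                     "n_sig2": r.n_sig2_detected, "s_score": r.s_score,
                     "category": r.category})
    return pd.DataFrame(rows)


def compare_category_frequencies(table, method: str = "auto",
                                 correction: bool = True) -> dict:
    """Compare category counts across groups on an r x c table.

    ``table`` is a 2-d array-like of counts (groups x categories).
    ``method``: "fisher" (2x2 only), "chi2", or "auto" (Fisher when the
    table is 2x2, chi-squared otherwise).  ``correction`` applies the
    Yates continuity correction to 2x2 chi-squared tests.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("need an r x c table with r, c >= 2")
    if (counts.sum(axis=1) == 0).any():
        raise ValidationError("empty group in contingency table")
    if method == "auto":
        method = "fisher" if counts.shape == (2, 2) else "chi2"
    if method == "fisher":
        if counts.shape != (2, 2):
            raise ValidationError("Fisher exact test supported for 2x2 only")
        _, p = fisher_exact(counts)
        return {"method": "fisher", "p_value": float(p),
                "table": counts.astype(int).tolist()}
    if method == "chi2":
        stat, p, dof, _ = chi2_contingency(counts, correction=correction)
        return {"method": "chi2", "statistic": float(stat), "p_value": float(p),
                "dof": int(dof), "correction": bool(correction),
                "table": counts.astype(int).tolist()}
    raise ValidationError(f"unknown method {method!r}")
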