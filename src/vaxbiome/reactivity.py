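"""Positivity calling on immunoassay readouts and responder clustering.

Three positivity rules are implemented:

* multiplex PBMC panels — a per-analyte cohort-derived delta threshold
  combined with a strict stimulated/control ratio > 2 and a positive
  pre-to-post delta change;
* whole-blood multiplex panels — stimulated/control ratio > 2 alone;
* whole-blood IFN-gamma release — fixed 0.08 IU/mL threshold logic.

Samples are then clustered on their binary call profiles with the
asymmetric binary (Jaccard) distance and Ward.D2 linkage, cut at two
clusters; the cluster with the higher mean positivity frequency is
labelled 1 (reactive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ModelError, ValidationError
from .io import CytokinePanel


@dataclass
class ReactivityResult:
    calls: pd.DataFrame            # sample x retained analyte, bool
    retained_analytes: list[str]
    cluster: pd.Series             # sample -> {0, 1}; 1 = reactive
    linkage: np.ndarray | None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# positivity rules
# ---------------------------------------------------------------------------


def call_positivity_multiplex(panel: CytokinePanel,
                              ratio_threshold: float = 2.0,
                              control_floor: float = 0.01) -> pd.DataFrame:
    """Cohort-thresholded positivity for paired pre/post multiplex panels.

    A sample is positive for an analyte when all three hold (strictly):
    delta > |smallest cohort delta for that analyte| / 2, ratio > 2, and
    post-delta minus pre-delta > 0.  The delta threshold is computed per
    analyte across all cohort samples at the post timepoint; when every
    delta is positive the smallest (positive) delta / 2 is used.
    """
    if not panel.has_pre:
        raise ValidationError(
            "multiplex positivity requires paired pre-vaccination values")
    delta = panel.stimulated - panel.control
    threshold = delta.min(axis=0).abs() / 2.0  # |min|/2 covers both sign cases
    ratio = panel.stimulated / panel.control.clip(lower=control_floor)
    pre_delta = panel.pre_stimulated - panel.pre_control
    calls = (delta.gt(threshold, axis=1)
             & (ratio > ratio_threshold)
             & ((delta - pre_delta) > 0))
    return calls


def call_positivity_wholeblood_ratio(panel: CytokinePanel,
                                     ratio_threshold: float = 2.0,
                                     control_floor: float = 0.01) -> pd.DataFrame:
    """Positivity = stimulated/control strictly above the ratio threshold.

    A zero control is replaced by ``control_floor``; a sample with both
    concentrations zero is negative.
    """
    ratio = panel.stimulated / panel.control.clip(lower=control_floor)
    calls = ratio > ratio_threshold
    calls &= panel.stimulated > 0
    return calls


def call_vidas_ifng(test_conc, nil_conc, threshold: float = 0.08):
    """Fixed-threshold IFN-gamma release call (IU/mL scale).

    Positive iff (test > threshold and nil < threshold) or
    (test - nil > threshold).  Accepts scalars or aligned arrays.
    """
    test = np.asarray(test_conc, dtype=float)
    nil = np.asarray(nil_conc, dtype=float)
    if (test < 0).any() or (nil < 0).any():
        raise ValidationError("concentrations must be >= 0")
    pos = ((test > threshold) & (nil < threshold)) | ((test - nil) > threshold)
    if np.isscalar(test_conc) and np.isscalar(nil_conc):
        return bool(pos)
    return pos


# ---------------------------------------------------------------------------
# analyte filtering and clustering
# ---------------------------------------------------------------------------


def filter_low_frequency(calls: pd.DataFrame, cutoff: float = 0.10) -> list[str]:
    """Analytes kept for clustering: positivity frequency >= cutoff.

    "Less than cutoff" is excluded, so an analyte at exactly the cutoff
    is retained.
    """
    freq = calls.mean(axis=0)
    retained = list(freq.index[freq >= cutoff])
    if not retained:
        raise ModelError("no analytes retained for clustering")
    return retained


def _binary_distance(calls: np.ndarray) -> np.ndarray:
    """Asymmetric binary (Jaccard) condensed distance; double zeros ignored."""
    with np.errstate(invalid="ignore"):
        d = pdist(calls.astype(bool), metric="jaccard")
    return np.nan_to_num(d, nan=0.0)  # two all-negative samples are identical


def cluster_reactivity(calls: pd.DataFrame,
                       retained_analytes: list[str] | None = None
                       ) -> ReactivityResult:
    """Two-cluster Ward.D2 cut of the binary-distance sample dendrogram."""
    if retained_analytes is not None:
        calls = calls[retained_analytes]
    else:
        retained_analytes = list(calls.columns)
    if calls.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    if calls.shape[1] < 1:
        raise ValidationError("clustering needs at least 1 analyte")

    mat = calls.to_numpy(dtype=bool)
    d = _binary_distance(mat)
    if np.allclose(d, 0.0):
        # all call profiles identical: no meaningful split
        label = int(mat.mean() > 0.5)
        cluster = pd.Series(label, index=calls.index, name="cluster")
        return ReactivityResult(calls=calls, retained_analytes=retained_analytes,
                                cluster=cluster, linkage=None, degenerate=True)

    # scipy's 'ward' on a precomputed dissimilarity implements the
    # Lance-Williams recurrence on squared distances (the ward.D2 convention)
    Z = linkage(d, method="ward")
    assign = fcluster(Z, t=2, criterion="maxclust")
    freq = {c: mat[assign == c].mean() for c in np.unique(assign)}
    reactive = max(freq, key=lambda c: freq[c])
    cluster = pd.Series((assign == reactive).astype(int), index=calls.index,
                        name="cluster")
    return ReactivityResult(calls=calls, retained_analytes=retained_analytes,
                            cluster=cluster, linkage=Z)


# ---------------------------------------------------------------------------
# scalar-readout group constructions
# ---------------------------------------------------------------------------


def median_split(scores: pd.Series, median: float | None = None) -> pd.Series:
    """Binary groups by median: score > median -> 1, score <= median -> 0.

    Ties at the median go to group 0 (the conservative, non-reactive
    side).  An externally supplied median (e.g. a published cohort
    median) overrides the sample median.
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 2:
        raise ValidationError("median split needs at least 2 subjects")
    if scores.nunique() == 1 and median is None:
        raise ModelError("no split possible: all scores equal")
    if median is None:
        median = float(np.median(scores))
    return (scores > median).astype(int).rename("cluster")


def call_booster_response(pre_titer, post_titer, fold: float = 2.0,
                          min_titer: float = 20.0):
    """Booster responder call: post/pre > fold and post > min_titer.

    A zero pre-booster titer makes the fold criterion vacuously true
    (fold treated as +inf), leaving the absolute-titer criterion to
    decide.
    """
    pre = np.asarray(pre_titer, dtype=float)
    post = np.asarray(post_titer, dtype=float)
    if (pre < 0).any() or (post < 0).any():
        raise ValidationError("titers must be >= 0")
    with np.errstate(divide="ignore"):
        fold_ok = np.where(pre > 0, post > fold * pre, post > 0)
    resp = fold_ok & (post > min_titer)
    if np.isscalar(pre_titer) and np.isscalar(post_titer):
        return bool(resp)
    return resp
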