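"""Scoring predictions against a known composition.

Strain-level precision/recall/F1 count exact strain identities; the
cluster-level variant counts a prediction as correct when it falls in the
same cluster as a truth strain.  Abundance profiles are compared with the
base-2 Jensen-Shannon divergence, which lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon

from .errors import InputError


@dataclass
class EvalReport:
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    f1: float


def prf(
    truth: set[str],
    predicted: set[str],
    level: str = "strain",
    cluster_map: dict[str, str] | None = None,
) -> EvalReport:
    """Precision/recall/F1 at strain or cluster level.

    At cluster level, truth and predictions are mapped through
    ``cluster_map`` first, so any representative of the right cluster counts
    as a true positive.  Ratios with an empty denominator are reported as 0.
    """
    if not truth:
        raise InputError("truth set must be non-empty")
    if level == "cluster":
        if cluster_map is None:
            raise InputError("cluster-level evaluation needs a cluster map")
        missing = sorted((truth | predicted) - set(cluster_map))
        if missing:
            raise InputError(f"strains absent from cluster map: {missing}")
        truth = {cluster_map[s] for s in truth}
        predicted = {cluster_map[s] for s in predicted}
    elif level != "strain":
        raise InputError(f"unknown level {level!r}")
    tp = len(truth & predicted)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    return EvalReport(TP=tp, FP=fp, FN=fn, precision=precision, recall=recall, f1=f1)


def jsd(T, P) -> float:
    """Base-2 Jensen-Shannon divergence of two abundance vectors.

    The shorter vector is zero-padded; each input must be non-negative and
    sum to 1 (tolerance 1e-9).
    """
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if T.ndim != 1 or P.ndim != 1:
        raise InputError("abundance vectors must be one-dimensional")
    if (T < 0).any() or (P < 0).any():
        raise InputError("abundances must be non-negative")
    for name, v in (("T", T), ("P", P)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise InputError(f"{name} must sum to 1, got {v.sum()!r}")
    n = max(T.size, P.size)
    T = np.pad(T, (0, n - T.size))
    P = np.pad(P, (0, n - P.size))
    return float(jensenshannon(T, P, base=2) ** 2)


def jsd_profiles(
    truth: dict[str, float], predicted: dict[str, float], align: str = "ids"
) -> float:
    """JSD between two id-keyed profiles.

    ``align='ids'`` matches entries by strain id (missing ids get 0);
    ``align='pad'`` compares the value vectors positionally, padding the
    shorter with zeros.
    """
    if align == "ids":
        ids = sorted(set(truth) | set(predicted))
        T = np.array([truth.get(i, 0.0) for i in ids])
        P = np.array([predicted.get(i, 0.0) for i in ids])
    elif align == "pad":
        T = np.array(list(truth.values()))
        P = np.array(list(predicted.values()))
    else:
        raise InputError(f"unknown alignment {align!r}")
    return jsd(T, P)
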