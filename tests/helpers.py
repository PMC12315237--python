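"""Shared test factories and independent metric oracles."""

import numpy as np

from l2cforecast.cohort import BaselineProfile, ParticipantHistory, VisitRecord, normalize_by_icv


def make_visit(pid="P1", month=0.0, **kwargs):
    """Visit factory with ICV normalization applied when volumes are given."""
    visit = VisitRecord(participant_id=pid, month=month, **kwargs)
    return normalize_by_icv(visit)


def make_history(visit_specs, pid="P1", baseline=None):
    baseline = baseline or BaselineProfile(sex="female", education_years=16.0,
                                           marital="married", apoe4_count=1)
    visits = tuple(make_visit(pid=pid, **spec) for spec in visit_specs)
    return ParticipantHistory(pid, baseline, visits)


def pairwise_auc(scores, labels):
    """O(n^2) rank-count AUC with half-credit for ties (independent oracle)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def pairwise_mauc(probs, truth):
    """Mean one-vs-rest pairwise AUC over the computable classes."""
    probs = np.asarray(probs, dtype=float)
    truth = np.asarray(truth, dtype=float)
    aucs = []
    for c in (0, 1, 2):
        labels = truth == c
        if labels.any() and (~labels).any():
            aucs.append(pairwise_auc(probs[:, c], labels))
    return float(np.mean(aucs))
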