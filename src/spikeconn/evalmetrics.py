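"""Scoring estimated connection matrices against ground truth.

Detection quality is summarized per sign category (excitatory,
inhibitory) with one-vs-rest confusion counts and the Matthews
correlation coefficient

    MCC = (N_TP·N_TN − N_FP·N_FN) /
          √[(N_TP+N_FP)(N_TP+N_FN)(N_TN+N_FP)(N_TN+N_FN)],

macro-averaged over the two categories, MCC = (MCC_E + MCC_I)/2.  True
excitatory connections weaker than a visibility threshold (0.1 mV by
default) are excluded from the excitatory tally: they are inherently
undetectable at realistic recording lengths, and detections of them are
not penalized as false positives either.

The E–I dominance index d_ei = (n_e − n_i)/(n_e + n_i) classifies a
unit from its detected outgoing connections as putative excitatory
(> 0), putative inhibitory (< 0) or undetermined (no detections or 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netsim import GroundTruthNetwork, SpikeTrainSet

__all__ = [
    "ConfusionSummary",
    "confusion",
    "macro_mcc",
    "threshold_sweep",
    "ei_dominance",
    "duration_curve",
    "split_half_stability",
]


@dataclass(frozen=True)
class ConfusionSummary:
    counts: dict  # {'E': {'TP':..,'FP':..,'TN':..,'FN':..}, 'I': {...}}
    mcc_e: float
    mcc_i: float
    macro: float
    fpr: dict  # false positive (discovery) rate per category
    fnr: dict  # false negative (omission) rate per category
    psp_visibility_threshold: float


def _safe_mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Binary MCC, guarded to 0 when any marginal is empty."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _est_sign_map(est: pd.DataFrame) -> dict[tuple[int, int], str]:
    """Detected sign per ordered pair from an estimate table.

    Accepts the CNN table (connected, psp_mV) or the GLM table
    (significant, J): sign is that of the detected strength.
    """
    if "connected" in est.columns:
        det_col, val_col = "connected", "psp_mV"
    elif "significant" in est.columns:
        det_col, val_col = "significant", "J"
    else:
        raise ValueError("estimate table lacks 'connected'/'significant'")
    out = {}
    for r in est.itertuples():
        if getattr(r, det_col):
            v = getattr(r, val_col)
            out[(int(r.pre), int(r.post))] = "E" if v > 0 else "I"
    return out


def confusion(est: pd.DataFrame, truth: GroundTruthNetwork,
              psp_threshold: float = 0.1) -> ConfusionSummary:
    """One-vs-rest confusion counts and MCCs over all estimated pairs.

    Every ordered pair present in ``est`` is evaluated.  In the
    excitatory category, pairs whose true connection is excitatory but
    weaker than ``psp_threshold`` (mV) are dropped from the tally
    entirely (neither FN nor FP).
    """
    units = set(int(u) for u in set(est["pre"]).union(est["post"]))
    if units and max(units) >= truth.n_units:
        raise ValueError("estimate table refers to units outside the truth network")
    truth_sign = {}
    truth_psp = {}
    for r in truth.table.itertuples():
        key = (int(r.pre), int(r.post))
        if key[0] in units and key[1] in units:
            truth_sign[key] = r.sign
            truth_psp[key] = abs(float(r.psp_mV))
    est_sign = _est_sign_map(est)
    all_pairs = [(int(r.pre), int(r.post)) for r in est.itertuples()]
    if len(set(all_pairs)) != len(all_pairs):
        raise ValueError("duplicate ordered pairs in estimate table")

    counts = {}
    for cat in ("E", "I"):
        tp = fp = tn = fn = 0
        for key in all_pairs:
            t_sign = truth_sign.get(key)
            if (cat == "E" and t_sign == "E"
                    and truth_psp[key] < psp_threshold):
                continue  # invisible excitatory connection: ignored
            is_pos = t_sign == cat
            is_det = est_sign.get(key) == cat
            if is_pos and is_det:
                tp += 1
            elif is_pos:
                fn += 1
            elif is_det:
                fp += 1
            else:
                tn += 1
        counts[cat] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}

    mcc_e = _safe_mcc(**{k.lower(): v for k, v in counts["E"].items()})
    mcc_i = _safe_mcc(**{k.lower(): v for k, v in counts["I"].items()})
    fpr = {}
    fnr = {}
    for cat in ("E", "I"):
        c = counts[cat]
        fpr[cat] = c["FP"] / (c["FP"] + c["TP"]) if c["FP"] + c["TP"] else 0.0
        fnr[cat] = c["FN"] / (c["FN"] + c["TP"]) if c["FN"] + c["TP"] else 0.0
    return ConfusionSummary(counts=counts, mcc_e=mcc_e, mcc_i=mcc_i,
                            macro=(mcc_e + mcc_i) / 2.0, fpr=fpr, fnr=fnr,
                            psp_visibility_threshold=psp_threshold)


def macro_mcc(summary: ConfusionSummary) -> float:
    """Macro-average MCC = (MCC_E + MCC_I)/2."""
    return (summary.mcc_e + summary.mcc_i) / 2.0


def threshold_sweep(model, spikes: SpikeTrainSet, truth: GroundTruthNetwork,
                    thetas=None, psp_threshold: float = 0.1,
                    **estimate_kwargs) -> pd.DataFrame:
    """Macro MCC of a CNN estimator as a function of the threshold θ.

    The correlograms are evaluated once; each θ re-thresholds the z
    outputs.  Returns a DataFrame (theta, macro_mcc, n_detected).
    """
    from .cnn_estimator import estimate_matrix

    if thetas is None:
        thetas = np.round(np.arange(0.05, 1.0, 0.05), 3)
    base = estimate_matrix(model, spikes, theta=-np.inf, **estimate_kwargs)
    rows = []
    for theta in thetas:
        est = base.copy()
        est["connected"] = est["z"] > theta
        est.loc[~est["connected"], "psp_mV"] = 0.0
        summary = confusion(est, truth, psp_threshold)
        rows.append({"theta": float(theta), "macro_mcc": summary.macro,
                     "n_detected": int(est["connected"].sum())})
    return pd.DataFrame(rows)


def ei_dominance(est: pd.DataFrame) -> pd.DataFrame:
    """Per-unit E–I dominance index over detected outgoing connections.

    Returns a DataFrame (unit, n_e, n_i, d_ei, classification) where
    d_ei is NaN and the classification 'undetermined' when a unit has
    no detections (or when the index is exactly 0).
    """
    est_sign = _est_sign_map(est)
    units = sorted(set(est["pre"]).union(est["post"]))
    rows = []
    for u in units:
        n_e = sum(1 for (p, _), s in est_sign.items() if p == u and s == "E")
        n_i = sum(1 for (p, _), s in est_sign.items() if p == u and s == "I")
        if n_e + n_i == 0:
            d = float("nan")
            label = "undetermined"
        else:
            d = (n_e - n_i) / (n_e + n_i)
            label = ("excitatory" if d > 0
                     else "inhibitory" if d < 0 else "undetermined")
        rows.append({"unit": int(u), "n_e": n_e, "n_i": n_i, "d_ei": d,
                     "classification": label})
    return pd.DataFrame(rows)


def duration_curve(spikes: SpikeTrainSet, truth: GroundTruthNetwork,
                   estimator_fn, durations=(600.0, 1800.0, 7200.0),
                   psp_threshold: float = 0.1) -> pd.DataFrame:
    """FP/FN counts per sign category for truncated recording lengths.

    ``estimator_fn(spike_subset) -> estimate table`` is run on the
    recording truncated to each duration (seconds).  Longer recordings
    reveal weaker synapses, so excitatory FN counts should fall with
    duration while FP counts stay roughly flat.
    """
    rows = []
    for T in durations:
        if T <= 0:
            raise ValueError("durations must be positive")
        if T > spikes.duration:
            raise ValueError(f"duration {T} s exceeds recording span")
        est = estimator_fn(spikes.truncate(T))
        summary = confusion(est, truth, psp_threshold)
        for cat in ("E", "I"):
            rows.append({"duration_s": T, "category": cat,
                         "FP": summary.counts[cat]["FP"],
                         "FN": summary.counts[cat]["FN"],
                         "TP": summary.counts[cat]["TP"]})
    return pd.DataFrame(rows)


def split_half_stability(spikes: SpikeTrainSet, estimator_fn) -> float:
    """Sign agreement between estimates from the two recording halves.

    Runs the estimator on [0, T/2) and [T/2, T) separately and returns
    the fraction of ordered pairs detected in *both* halves whose
    estimated signs agree.  NaN when no pair is detected twice.
    """
    half = spikes.duration / 2.0
    first = spikes.truncate(half)
    shifted = SpikeTrainSet(
        spikes.unit_ids,
        [t[t >= half] - half for t in spikes.trains],
        half, spikes.meta)
    s1 = _est_sign_map(estimator_fn(first))
    s2 = _est_sign_map(estimator_fn(shifted))
    both = set(s1) & set(s2)
    if not both:
        return float("nan")
    return sum(s1[k] == s2[k] for k in both) / len(both)
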