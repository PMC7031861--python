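"""ROC / MCC / FDR evaluation of score tracks against known sites.

Detection is framed as ranking: score values are sorted in descending
order, every distinct value is tried as a call threshold (call iff
score >= threshold), and the operating point maximizing the Matthews
correlation coefficient is reported together with its empirical false
discovery rate FP / (FP + TP).

2'-O-methylated (Nm) positions are the positives; pseudouridines and
other modified residues are negatives by default — ligation bias at a
pseudouridine produces an Nm-like gap, so these sites are exactly the
false-positive source the evaluation must expose. An option removes them
from the universe for sensitivity analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rms.scoring import ScoreTrack

logger = logging.getLogger(__name__)

STATUSES = ("Nm", "psi", "other_mod")
UNMODIFIED = "unmod"


@dataclass
class SiteAnnotation:
    """Modification status per annotated position; everything else is unmodified.

    ``sites`` is a DataFrame with columns ``ref``, ``pos`` (1-based) and
    ``status`` in {Nm, psi, other_mod}; one annotation may cover several
    references.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.sites, columns=["ref", "pos", "status"]).copy()
        df["pos"] = df["pos"].astype(int)
        bad = set(df["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown status values {sorted(bad)}; allowed {STATUSES}")
        if (df["pos"] < 1).any():
            raise ValueError("annotation positions must be >= 1")
        if df.duplicated(["ref", "pos"]).any():
            dupes = df[df.duplicated(["ref", "pos"])][["ref", "pos"]]
            raise ValueError(f"duplicate annotated positions: {dupes.values.tolist()}")
        self.sites = df.reset_index(drop=True)

    def for_ref(self, ref: str) -> dict[int, str]:
        sub = self.sites[self.sites["ref"] == ref]
        return dict(zip(sub["pos"], sub["status"]))

    def counts(self) -> dict[str, int]:
        return self.sites["status"].value_counts().to_dict()


def load_annotation(path) -> SiteAnnotation:
    """Read a ``ref<TAB>pos<TAB>status`` annotation table."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["ref", "pos", "status"],
        dtype={"ref": str, "status": str},
    )
    return SiteAnnotation(df)


def save_annotation(annotation: SiteAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("#ref\tpos\tstatus\n")
        for row in annotation.sites.itertuples(index=False):
            fh.write(f"{row.ref}\t{row.pos}\t{row.status}\n")


def label_positions(
    track: ScoreTrack,
    annotation: SiteAnnotation,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Attach a modification status to every valid scored position.

    Returns a DataFrame (ref, pos, score, status); unannotated positions
    get status ``unmod``. Annotated sites falling on masked or
    out-of-range positions are excluded with a warning and tallied in
    ``df.attrs['excluded_sites']``; statuses in ``exclude`` are dropped
    from the universe entirely.
    """
    status_by_pos = annotation.for_ref(track.ref_name)
    positions = track.positions()
    scores = track.valid_values()
    statuses = [status_by_pos.get(int(p), UNMODIFIED) for p in positions]
    valid_set = set(int(p) for p in positions)
    excluded = [
        (track.ref_name, pos, st)
        for pos, st in status_by_pos.items()
        if pos not in valid_set
    ]
    for ref, pos, st in excluded:
        logger.warning(
            "annotated %s site at %s:%d falls on a masked/out-of-range "
            "position and is excluded",
            st,
            ref,
            pos,
        )
    df = pd.DataFrame(
        {
            "ref": track.ref_name,
            "pos": positions,
            "score": scores,
            "status": statuses,
        }
    )
    if exclude:
        df = df[~df["status"].isin(set(exclude))].reset_index(drop=True)
    df.attrs["excluded_sites"] = excluded
    df.attrs["status_counts"] = df["status"].value_counts().to_dict()
    return df


def pool_labels(labeled: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Pool per-reference labeled positions into one ranked universe."""
    frames = list(labeled)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["excluded_sites"] = [
        site for f in frames for site in f.attrs.get("excluded_sites", [])
    ]
    return out


@dataclass
class OperatingPoint:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    tpr: float
    fpr: float
    mcc: float
    fdr: float


@dataclass
class RocResult:
    """Full threshold sweep plus the max-MCC operating point."""

    table: pd.DataFrame  # threshold, tp, fp, tn, fn, tpr, fpr, mcc
    auc: float
    best: OperatingPoint
    n_positive: int
    n_negative: int

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "max_mcc": self.best.mcc,
            "fdr": self.best.fdr,
            "threshold": self.best.threshold,
            "counts": {
                "tp": self.best.tp,
                "fp": self.best.fp,
                "tn": self.best.tn,
                "fn": self.best.fn,
            },
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }

    def save(self, roc_path=None, json_path=None) -> None:
        if roc_path is not None:
            self.table.to_csv(roc_path, sep="\t", index=False, float_format="%.10g")
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)
                fh.write("\n")


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def roc_mcc(labeled: pd.DataFrame, positive: str = "Nm") -> RocResult:
    """Threshold sweep over distinct score values with MCC per threshold.

    Ties in MCC are broken toward the higher threshold (fewer calls,
    conservative FDR). The AUC is the trapezoidal area of the resulting
    step ROC, which equals the Mann-Whitney two-sample statistic on the
    same labels.
    """
    scores = np.asarray(labeled["score"], dtype=float)
    y = np.asarray(labeled["status"] == positive)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"degenerate labels: {n_pos} positive / {n_neg} negative positions"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    ys = y[order]
    cum_tp = np.cumsum(ys)
    # last index of each run of tied scores = the state after calling
    # everything >= that value
    boundary = np.flatnonzero(np.diff(s) != 0)
    idx = np.concatenate([boundary, [len(s) - 1]])
    thresholds = s[idx]
    tp = cum_tp[idx]
    calls = idx + 1
    fp = calls - tp
    fn = n_pos - tp
    tn = n_neg - fp
    tpr = tp / n_pos
    fpr = fp / n_neg
    prod = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(divide="ignore", invalid="ignore"):
        mcc = np.where(prod > 0, (tp * tn - fp * fn) / np.sqrt(prod.astype(float)), 0.0)
    table = pd.DataFrame(
        {
            "threshold": thresholds,
            "tp": tp,
            "fp": fp,
            "tn": tn,
            "fn": fn,
            "tpr": tpr,
            "fpr": fpr,
            "mcc": mcc,
        }
    )
    auc = float(np.trapezoid(np.concatenate([[0.0], tpr]), np.concatenate([[0.0], fpr])))
    i = int(np.argmax(mcc))  # first occurrence = highest threshold on ties
    tp_i, fp_i = int(tp[i]), int(fp[i])
    fdr = fp_i / (fp_i + tp_i) if (fp_i + tp_i) > 0 else 0.0
    best = OperatingPoint(
        threshold=float(thresholds[i]),
        tp=tp_i,
        fp=fp_i,
        tn=int(tn[i]),
        fn=int(fn[i]),
        tpr=float(tpr[i]),
        fpr=float(fpr[i]),
        mcc=float(mcc[i]),
        fdr=float(fdr),
    )
    return RocResult(table=table, auc=auc, best=best, n_positive=n_pos, n_negative=n_neg)


def compare_runs(
    results: Sequence[RocResult],
    labels: Sequence[str],
    baseline: int = 0,
) -> pd.DataFrame:
    """Tabulate max MCC and FDR across runs, with deltas vs a baseline run.

    The window-size sweep experiment is this comparison applied to the
    evaluations of a ``score_sweep`` output.
    """
    if len(results) < 2:
        raise ValueError("need at least two results to compare")
    if len(results) != len(labels):
        raise ValueError("results and labels must have equal length")
    rows = []
    base = results[baseline]
    for label, res in zip(labels, results):
        rows.append(
            {
                "label": label,
                "max_mcc": res.best.mcc,
                "fdr": res.best.fdr,
                "threshold": res.best.threshold,
                "auc": res.auc,
                "delta_mcc": res.best.mcc - base.best.mcc,
                "delta_fdr": res.best.fdr - base.best.fdr,
            }
        )
    return pd.DataFrame(rows)
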