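"""Beta-level quality control for methylation matrices.

Order of operations is fixed and matters: (1) drop excluded probes,
(2) mask entries failing the detection-p threshold, (3) remove samples with
too many failed probes, (4) remove probes with too high a failure rate
computed over the surviving samples, (5) impute remaining missing entries by
probe-wise k-nearest-neighbour averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ProbeExclusionLists:
    """Named probe blacklists; lists may overlap (union semantics)."""

    non_cpg: list[str] = field(default_factory=list)
    snp_related: list[str] = field(default_factory=list)
    chr_y: list[str] = field(default_factory=list)
    trimodal: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, set[str]]:
        return {
            "non_cpg": set(self.non_cpg),
            "snp_related": set(self.snp_related),
            "chr_y": set(self.chr_y),
            "trimodal": set(self.trimodal),
        }


@dataclass
class QCReport:
    removed_probes_per_list: dict[str, int] = field(default_factory=dict)
    masked_entries: int = 0
    removed_samples: list[str] = field(default_factory=list)
    removed_probes: list[str] = field(default_factory=list)
    imputed_entries: int = 0

    def summary(self) -> str:
        lines = ["QC report", "---------"]
        for name, count in self.removed_probes_per_list.items():
            lines.append(f"excluded probes ({name}): {count}")
        lines.append(f"masked entries (detection p): {self.masked_entries}")
        lines.append(f"removed samples (> failure threshold): {len(self.removed_samples)}")
        lines.append(f"removed probes (> failure threshold): {len(self.removed_probes)}")
        lines.append(f"imputed entries: {self.imputed_entries}")
        return "\n".join(lines)


def apply_exclusion_lists(
    beta: pd.DataFrame, lists: ProbeExclusionLists, report: QCReport | None = None
) -> pd.DataFrame:
    """Drop all probes in the union of the exclusion lists (set semantics)."""
    report = report if report is not None else QCReport()
    present = set(beta.index)
    union: set[str] = set()
    for name, ids in lists.as_dict().items():
        report.removed_probes_per_list[name] = len(ids & present)
        union |= ids
    keep = ~beta.index.isin(union)
    return beta.loc[keep]


def mask_and_filter(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame,
    p_thresh: float = 0.01,
    sample_fail_thresh: float = 0.10,
    probe_fail_thresh: float = 0.10,
) -> tuple[pd.DataFrame, QCReport]:
    """Mask failed entries and drop failing samples, then failing probes.

    An entry fails when its detection p exceeds ``p_thresh``.  Samples with
    strictly more than ``sample_fail_thresh`` failed probes are removed
    first; probe failure rates are then recomputed over the surviving
    samples and probes strictly above ``probe_fail_thresh`` are removed.
    Failed entries of survivors are returned as NaN.
    """
    if not beta.index.equals(detection_p.index) or not beta.columns.equals(
        detection_p.columns
    ):
        raise ValueError("beta and detection-p matrices must share their index")
    report = QCReport()
    failed = detection_p.to_numpy() > p_thresh
    report.masked_entries = int(failed.sum())

    sample_fail = failed.mean(axis=0)
    keep_samples = sample_fail <= sample_fail_thresh
    report.removed_samples = list(beta.columns[~keep_samples])
    if not keep_samples.any():
        raise ValueError("all samples removed by detection-p filtering")

    failed = failed[:, keep_samples]
    probe_fail = failed.mean(axis=1)
    keep_probes = probe_fail <= probe_fail_thresh
    report.removed_probes = list(beta.index[~keep_probes])

    out = beta.loc[keep_probes, keep_samples].copy()
    out[failed[keep_probes]] = np.nan
    return out, report


def impute_knn(
    beta: pd.DataFrame, k: int = 10, report: QCReport | None = None
) -> pd.DataFrame:
    """Fill missing entries from the k nearest probes.

    For each missing (probe, sample) entry the imputed value is the plain
    mean, over the ``k`` probes closest in Euclidean distance (computed on
    samples where both probes are observed), of those probes' values in that
    sample.  Neighbours missing at the target sample are skipped in favour
    of the next nearest.  Non-missing entries are never altered.
    """
    X = beta.to_numpy(dtype=float).copy()
    missing = np.isnan(X)
    if not missing.any():
        return beta.copy()
    if missing.mean() >= 0.5:
        raise ValueError("more than 50% of entries missing; refusing to impute")
    all_missing = missing.all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"probe(s) entirely missing: {list(beta.index[all_missing])}"
        )
    n_probes = X.shape[0]
    k = min(k, n_probes - 1)
    target_rows = np.flatnonzero(missing.any(axis=1))
    filled = X.copy()
    for r in target_rows:
        obs_r = ~missing[r]
        # distances to every other probe over commonly observed samples
        diff = X[:, obs_r] - X[r, obs_r]
        common = ~missing[:, obs_r]
        diff = np.where(common, diff, 0.0)
        n_common = common.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1))
        dist[r] = np.inf
        dist[n_common == 0] = np.inf
        order = np.argsort(dist, kind="stable")
        for c in np.flatnonzero(missing[r]):
            vals = []
            for q in order:
                if not np.isfinite(dist[q]):
                    break
                if not missing[q, c]:
                    vals.append(X[q, c])
                    if len(vals) == k:
                        break
            if not vals:
                raise ValueError(
                    f"no observed neighbour for probe {beta.index[r]!r} at "
                    f"sample {beta.columns[c]!r}"
                )
            filled[r, c] = float(np.mean(vals))
    if report is not None:
        report.imputed_entries = int(missing.sum())
    return pd.DataFrame(filled, index=beta.index, columns=beta.columns)
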