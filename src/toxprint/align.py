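"""Cross-spectrum peak matching into a consensus table, replicate summaries.

Peak masses pooled over all samples are single-linkage clustered with a
mass-dependent tolerance; each cluster becomes one consensus peak whose row
holds every sample's apex abundance (0 mV where a sample shows no peak, so
paired statistics stay defined). Letter labels follow ascending mass.
"""

from __future__ import annotations

from dataclasses import dataclass
import string

import numpy as np
import pandas as pd

from .peaks import PeakList
from .synth import ExperimentDesign

__all__ = ["ConsensusPeakTable", "ConditionSummary", "match_peaks", "summarize_conditions"]


def _letter_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... in ascending mass order."""
    letters = string.ascii_uppercase
    labels = []
    for i in range(n):
        label = ""
        k = i
        while True:
            label = letters[k % 26] + label
            k = k // 26 - 1
            if k < 0:
                break
        labels.append(label)
    return labels


def _cluster_masses(masses: np.ndarray, tol_da: float, tol_ppm: float):
    """1-D single linkage: sort, cut where the gap exceeds the local tolerance.

    Returns (labels aligned to the input order, cluster median masses).
    """
    if masses.size == 0:
        return np.array([], dtype=int), np.array([])
    order = np.argsort(masses, kind="stable")
    sorted_masses = masses[order]
    gaps = np.diff(sorted_masses)
    midpoints = 0.5 * (sorted_masses[1:] + sorted_masses[:-1])
    thresholds = np.maximum(tol_da, tol_ppm * 1e-6 * midpoints)
    cluster_of_sorted = np.concatenate([[0], np.cumsum(gaps > thresholds)])
    labels = np.empty(masses.size, dtype=int)
    labels[order] = cluster_of_sorted
    medians = np.array(
        [np.median(sorted_masses[cluster_of_sorted == c]) for c in range(cluster_of_sorted[-1] + 1)]
    )
    return labels, medians


@dataclass
class ConsensusPeakTable:
    """Peaks x samples abundance matrix with consensus masses and labels."""

    abundance: pd.DataFrame       # index: label; columns: sample_id; values mV
    consensus_masses: np.ndarray  # aligned to the index
    sample_conditions: dict       # sample_id -> condition key
    sample_replicates: dict       # sample_id -> replicate index (pairing key)

    def __post_init__(self) -> None:
        if len(self.consensus_masses) != len(self.abundance):
            raise ValueError("one consensus mass per table row required")
        if self.abundance.index.duplicated().any():
            raise ValueError("labels must be unique")

    @property
    def labels(self) -> list[str]:
        return list(self.abundance.index)

    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)


def match_peaks(
    peaklists: list[PeakList], tol_da: float = 2.0, tol_ppm: float = 500.0
) -> ConsensusPeakTable:
    """Match peak masses across samples into a consensus peaks-x-samples table.

    If a sample contributes more than one peak to a cluster the tallest is
    kept. Absent peaks enter as 0 mV.
    """
    if not peaklists:
        raise ValueError("need at least one peak list")
    pooled_mass, pooled_ab, pooled_sample = [], [], []
    for pl in peaklists:
        for p in pl.peaks:
            pooled_mass.append(p.mass)
            pooled_ab.append(p.abundance)
            pooled_sample.append(pl.sample_id)
    pooled_mass = np.asarray(pooled_mass, dtype=float)
    labels, medians = _cluster_masses(pooled_mass, tol_da, tol_ppm)

    sample_ids = [pl.sample_id for pl in peaklists]
    matrix = pd.DataFrame(0.0, index=range(len(medians)), columns=sample_ids)
    for cid, ab, sid in zip(labels, pooled_ab, pooled_sample):
        if ab > matrix.at[cid, sid]:
            matrix.at[cid, sid] = ab

    order = np.argsort(medians)
    matrix = matrix.iloc[order].reset_index(drop=True)
    consensus = medians[order]
    matrix.index = pd.Index(_letter_labels(len(consensus)), name="label")
    conditions = {
        pl.sample_id: (pl.condition.key if pl.condition is not None else "")
        for pl in peaklists
    }
    replicates = {pl.sample_id: pl.replicate_index for pl in peaklists}
    return ConsensusPeakTable(
        abundance=matrix,
        consensus_masses=consensus,
        sample_conditions=conditions,
        sample_replicates=replicates,
    )


def consensus_from_abundances(abundances: pd.DataFrame) -> ConsensusPeakTable:
    """Build a consensus table directly from a tidy abundance frame.

    Expects columns (sample_id, condition, replicate, true_mass, abundance)
    as produced by the abundance-level generator; each distinct mass becomes
    one consensus row. Bypasses spectral rendering and detection, for tests
    and calibration studies of the downstream statistics alone.
    """
    wide = abundances.pivot(index="true_mass", columns="sample_id", values="abundance")
    wide = wide.fillna(0.0).sort_index()
    masses = wide.index.to_numpy(dtype=float)
    wide.index = pd.Index(_letter_labels(len(wide)), name="label")
    meta = abundances.drop_duplicates("sample_id").set_index("sample_id")
    return ConsensusPeakTable(
        abundance=wide,
        consensus_masses=masses,
        sample_conditions=meta["condition"].to_dict(),
        sample_replicates=meta["replicate"].to_dict(),
    )


@dataclass
class ConditionSummary:
    """Mean/SD/n of abundances per condition x consensus peak."""

    table: pd.DataFrame  # tidy: label, mass, condition, mean, sd, n
    replicate_abundance: pd.DataFrame  # label x sample with condition metadata

    def condition_means(self) -> pd.DataFrame:
        """Wide view: rows = labels, columns = condition keys, values = mean mV."""
        return self.table.pivot(index="label", columns="condition", values="mean")


def summarize_conditions(
    table: ConsensusPeakTable, design: ExperimentDesign
) -> ConditionSummary:
    """Per condition x peak: mean, sample SD, and replicate count.

    Missing detections already sit at 0 mV in the consensus table and are
    averaged in as such.
    """
    known = {c.key for c in design.conditions}
    rows = []
    sample_cond = table.sample_conditions
    for sid in table.sample_ids():
        cond = sample_cond.get(sid, "")
        if cond not in known:
            raise ValueError(f"sample {sid!r} has condition {cond!r} not in the design")
    for cond in known:
        cols = [s for s in table.sample_ids() if sample_cond[s] == cond]
        if not cols:
            continue
        sub = table.abundance[cols]
        means = sub.mean(axis=1)
        sds = sub.std(axis=1, ddof=1) if len(cols) > 1 else pd.Series(0.0, index=sub.index)
        for label, mass in zip(table.labels, table.consensus_masses):
            rows.append(
                {
                    "label": label,
                    "mass": float(mass),
                    "condition": cond,
                    "mean": float(means[label]),
                    "sd": float(sds[label]) if len(cols) > 1 else 0.0,
                    "n": len(cols),
                }
            )
    tidy = pd.DataFrame(rows, columns=["label", "mass", "condition", "mean", "sd", "n"])
    if len(tidy):
        tidy = tidy.sort_values(["mass", "condition"]).reset_index(drop=True)
    return ConditionSummary(table=tidy, replicate_abundance=table.abundance)
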