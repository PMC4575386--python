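"""Marker statistics: control-normalised changes, Grubbs screening, paired t.

Per peak and toxin the replicate abundances at the comparison concentration
are compared with the paired control replicates: a single-pass Grubbs
screen per arm (alpha = 0.05, two-sided) removes at most one outlying
experiment, then a classical paired two-sample t-test gives the direction
arrow and the significance mark (* for p < 0.05, ** for p < 0.01). No
multiple-testing correction is applied across the peak panel: marks are
per-peak, exactly as in the tabulated fingerprint this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import ConditionSummary, ConsensusPeakTable
from .synth import ExperimentDesign

__all__ = [
    "grubbs_test",
    "grubbs_critical_value",
    "relative_change",
    "paired_t_test",
    "build_marker_table",
    "count_significant",
    "shared_and_specific",
    "MarkerTable",
    "RelativeChangeMatrix",
]


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2)) with
    t = t_{alpha/(2n), n-2}, the classical maximum-studentized-deviate bound.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values, alpha: float = 0.05) -> int | None:
    """Index of the single most extreme value if it is a significant outlier.

    Returns None when no value exceeds the two-sided critical bound or when
    the sample has zero spread. At most one index is flagged per call;
    iterate externally for repeated exclusion.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"Grubbs test requires n >= 3, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        return None
    deviations = np.abs(x - x.mean())
    idx = int(np.argmax(deviations))
    g = deviations[idx] / sd
    if g > grubbs_critical_value(x.size, alpha):
        return idx
    return None


@dataclass
class PairedTResult:
    t: float
    p: float
    direction: str  # 'up', 'down' or 'none'
    note: str = ""


def paired_t_test(treated, control) -> PairedTResult:
    """Classical paired two-sample t-test on replicate-matched abundances.

    Replicate i of the treated arm is paired with replicate i of its control
    (same independent experiment). Two-sided p; direction is the sign of the
    mean difference.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size != control.size:
        raise ValueError(
            f"arms must be replicate-paired: {treated.size} vs {control.size}"
        )
    if treated.size < 2:
        raise ValueError("paired t-test requires at least 2 pairs")
    diff = treated - control
    mean_diff = diff.mean()
    if np.all(diff == 0):
        return PairedTResult(t=0.0, p=1.0, direction="none", note="identical arms")
    if diff.std(ddof=1) == 0:
        # constant non-zero difference: infinitely significant in the limit
        direction = "up" if mean_diff > 0 else "down"
        return PairedTResult(
            t=float(np.sign(mean_diff) * np.inf),
            p=0.0,
            direction=direction,
            note="zero-variance differences",
        )
    res = stats.ttest_rel(treated, control)
    direction = "up" if mean_diff > 0 else "down"
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue), direction=direction)


@dataclass
class RelativeChangeMatrix:
    """Treated/control abundance ratios per peak x treatment condition."""

    ratios: pd.DataFrame       # index: label; columns: condition keys
    sds: pd.DataFrame          # propagated SD of the ratio (delta method)
    excluded: list             # labels with zero control mean, not normalisable
    scale: str = "ratio"       # 'ratio' (control = 1) or 'ratio-1' (control = 0)

    def to_scale(self, scale: str) -> "RelativeChangeMatrix":
        if scale == self.scale:
            return self
        if scale == "ratio-1" and self.scale == "ratio":
            return RelativeChangeMatrix(self.ratios - 1.0, self.sds, self.excluded, scale)
        if scale == "ratio" and self.scale == "ratio-1":
            return RelativeChangeMatrix(self.ratios + 1.0, self.sds, self.excluded, scale)
        raise ValueError(f"unknown scale {scale!r}")


def relative_change(
    summary: ConditionSummary, control_condition: str = "control", scale: str = "ratio"
) -> RelativeChangeMatrix:
    """Per-peak treated/control mean-abundance ratios.

    Peaks whose control mean is zero cannot be normalised; they are dropped
    from the matrix and reported in ``excluded``.
    """
    means = summary.condition_means()
    if control_condition not in means.columns:
        raise ValueError(f"control condition {control_condition!r} not in summary")
    control = means[control_condition]
    excluded = list(means.index[control == 0])
    keep = means.index[control != 0]
    treated_cols = [c for c in means.columns if c != control_condition]
    ratios = means.loc[keep, treated_cols].div(control[keep], axis=0)

    sds = summary.table.pivot(index="label", columns="condition", values="sd")
    ns = summary.table.pivot(index="label", columns="condition", values="n")
    # delta-method SD of the ratio, treating the control mean as the anchor
    rel_sds = sds.loc[keep, treated_cols].div(control[keep], axis=0)
    out = RelativeChangeMatrix(
        ratios=ratios, sds=rel_sds, excluded=excluded, scale="ratio"
    )
    _ = ns  # replicate counts currently informational only
    return out.to_scale(scale)


@dataclass
class MarkerTable:
    """Per peak x toxin differential results (fingerprint table analog)."""

    table: pd.DataFrame
    # columns: label, mass, toxin, mean_treated, mean_control, relative_change,
    #          t, p, direction, mark, note

    def __post_init__(self) -> None:
        bad = self.table[
            (self.table["mark"] == "*")
            & ~((self.table["p"] < 0.05) & (self.table["p"] >= 0.01))
        ]
        if len(bad):
            raise ValueError("mark '*' inconsistent with p-values")

    @property
    def toxins(self) -> tuple[str, ...]:
        return tuple(self.table["toxin"].unique())

    def marked_labels(self, toxin: str) -> set[str]:
        if self.table.empty:
            return set()
        if toxin not in set(self.table["toxin"]):
            raise KeyError(f"unknown toxin {toxin!r}")
        sel = (self.table["toxin"] == toxin) & (self.table["mark"] != "none")
        return set(self.table.loc[sel, "label"])

    def render(self) -> str:
        """Text rendering with arrow/asterisk notation, one row per peak."""
        arrows = {"up": "↑", "down": "↓", "none": "-"}
        toxins = list(dict.fromkeys(self.table["toxin"]))
        lines = ["label  mass      " + "  ".join(f"{t:>16s}" for t in toxins)]
        for (label, mass), grp in self.table.groupby(["label", "mass"], sort=False):
            cells = []
            for toxin in toxins:
                row = grp[grp["toxin"] == toxin]
                if row.empty:
                    cells.append(f"{'?':>16s}")
                    continue
                d = arrows[row["direction"].iloc[0]]
                m = row["mark"].iloc[0]
                cell = "-" if m == "none" else f"{d} {m}"
                cells.append(f"{cell:>16s}")
            lines.append(f"{label:<5s}  {mass:<8.0f}  " + "  ".join(cells))
        return "\n".join(lines)


def _mark_for_p(p: float, alphas: tuple[float, float]) -> str:
    loose, strict = alphas
    if p < strict:
        return "**"
    if p < loose:
        return "*"
    return "none"


def build_marker_table(
    table: ConsensusPeakTable,
    design: ExperimentDesign,
    alphas: tuple[float, float] = (0.05, 0.01),
    grubbs_alpha: float = 0.05,
    min_pairs: int = 3,
) -> MarkerTable:
    """Rebuild the marker fingerprint table from a consensus peak table.

    For each toxin the designated comparison concentration is tested against
    the control, pairing replicates by experiment index. A single-pass
    Grubbs screen per arm removes the replicate pair containing a flagged
    value; fewer than ``min_pairs`` surviving pairs marks the peak
    untestable rather than dropping it.
    """
    control_key = design.control.key
    sample_cond = table.sample_conditions
    sample_rep = table.sample_replicates

    def arm_values(cond_key: str, labels_row: str) -> pd.Series:
        cols = [s for s in table.sample_ids() if sample_cond[s] == cond_key]
        reps = [sample_rep[s] for s in cols]
        vals = table.abundance.loc[labels_row, cols]
        return pd.Series(vals.to_numpy(dtype=float), index=reps).sort_index()

    rows = []
    for toxin, conc in design.comparison.items():
        treated_key = f"{toxin}:{conc:g}"
        if not any(sample_cond[s] == treated_key for s in table.sample_ids()):
            raise ValueError(
                f"comparison condition {treated_key!r} has no samples in the table"
            )
        for label, mass in zip(table.labels, table.consensus_masses):
            treated = arm_values(treated_key, label)
            control = arm_values(control_key, label)
            common = treated.index.intersection(control.index)
            treated, control = treated[common], control[common]

            note = ""
            drop: set[int] = set()
            if len(common) >= 3:
                for arm in (treated, control):
                    idx = grubbs_test(arm.to_numpy(), alpha=grubbs_alpha)
                    if idx is not None:
                        drop.add(int(arm.index[idx]))
            if drop:
                note = f"grubbs excluded replicate(s) {sorted(drop)}"
                keep = [r for r in common if r not in drop]
                treated, control = treated[keep], control[keep]

            if len(treated) < min_pairs:
                rows.append(
                    {
                        "label": label, "mass": float(mass), "toxin": toxin,
                        "mean_treated": float(treated.mean()) if len(treated) else np.nan,
                        "mean_control": float(control.mean()) if len(control) else np.nan,
                        "relative_change": np.nan, "t": np.nan, "p": np.nan,
                        "direction": "none", "mark": "none",
                        "note": (note + "; " if note else "") + "untestable: too few pairs",
                    }
                )
                continue

            res = paired_t_test(treated.to_numpy(), control.to_numpy())
            mc = float(control.mean())
            rel = float(treated.mean()) / mc if mc != 0 else np.nan
            rows.append(
                {
                    "label": label, "mass": float(mass), "toxin": toxin,
                    "mean_treated": float(treated.mean()), "mean_control": mc,
                    "relative_change": rel, "t": res.t, "p": res.p,
                    "direction": res.direction if res.direction != "none" else "none",
                    "mark": _mark_for_p(res.p, alphas) if res.direction != "none" else "none",
                    "note": "; ".join(filter(None, [note, res.note])),
                }
            )
    columns = [
        "label", "mass", "toxin", "mean_treated", "mean_control",
        "relative_change", "t", "p", "direction", "mark", "note",
    ]
    df = pd.DataFrame(rows, columns=columns)
    if len(df):
        df = df.sort_values(["mass", "toxin"], kind="stable").reset_index(drop=True)
    return MarkerTable(table=df)


def compare_with_fixture(
    marker_table: MarkerTable, fixture, require_null: bool = False
) -> pd.Series:
    """Per fixture peak: does the rebuilt table reproduce its arrow pattern?

    Marker-table rows are matched to fixture rows by nearest consensus mass.
    A peak agrees when every fixture arrow is reproduced: the corresponding
    rebuilt cell is marked with the same direction. With ``require_null``
    the unmarked fixture cells must additionally stay unmarked, which at the
    per-test alpha of 0.05 fails on roughly one null cell per rebuilt table
    by construction.
    """
    agreement = {}
    mt = marker_table.table
    for _, row in fixture.table.iterrows():
        if mt.empty:
            agreement[row["label"]] = False
            continue
        nearest = (mt["mass"] - row["mass"]).abs().idxmin()
        mass = mt.loc[nearest, "mass"]
        sub = mt[mt["mass"] == mass]
        ok = abs(mass - row["mass"]) < 10.0
        for toxin in fixture.toxins:
            cell = sub[sub["toxin"] == toxin]
            want_marked = row[f"mark_{toxin}"] != "none"
            if cell.empty:
                ok = ok and not want_marked
                continue
            marked = cell["mark"].iloc[0] != "none"
            if want_marked:
                if not marked or cell["direction"].iloc[0] != row[f"direction_{toxin}"]:
                    ok = False
            elif require_null and marked:
                ok = False
        agreement[row["label"]] = ok
    return pd.Series(agreement)


def count_significant(table, toxin: str) -> int:
    """Number of peaks marked (any asterisk) for the given toxin.

    Accepts a MarkerTable or the packaged marker fixture; both expose
    ``marked_labels``.
    """
    return len(table.marked_labels(toxin))


def shared_and_specific(table) -> tuple[set, dict]:
    """Peaks marked for every toxin, and per-toxin exclusively marked peaks."""
    toxins = list(table.toxins)
    if len(toxins) < 2:
        only = toxins[0] if toxins else None
        marked = table.marked_labels(only) if only else set()
        return marked, {only: marked} if only else {}
    marked = {t: table.marked_labels(t) for t in toxins}
    shared = set.intersection(*marked.values())
    specific = {}
    for t in toxins:
        others = set.union(*(marked[o] for o in toxins if o != t))
        specific[t] = marked[t] - others
    return shared, specific
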