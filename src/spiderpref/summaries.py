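"""Per-participant preference summaries and the incoherency index.

Each participant contributes 12 trial values per (feature, instruction).
Three per-participant summaries are supported:

``mean``
    arithmetic mean of the 12 values;
``median``
    sample median (midpoint convention for even counts);
``mmpd``
    the *mean of the modal part of the distribution*: determine whether
    values fall more frequently strictly above or strictly below 0.5
    (exact 0.5 values are ignored in the count), then average only the
    values on the majority side, re-including the exact 0.5 values.  This
    damps the influence of occasional slips (mistakes, boredom) on the
    minority side.  When the two sides tie, all values are averaged.

The incoherency index of a participant for one feature is
``x = |p_D + p_H - 1|`` where ``p_D`` and ``p_H`` are the summarized
preferences under the dangerous and harmless instructions.  A perfectly
coherent participant sets harmless spiders specular to dangerous ones
(``p_H = 1 - p_D``), giving x = 0; x = 1 requires both settings at the
same extreme.
"""

from __future__ import annotations

import logging
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data_model import FEATURES, INSTRUCTIONS, CohortTable

__all__ = [
    "Statistic",
    "mmpd",
    "incoherency",
    "summarize_preferences",
    "incoherency_table",
    "grand_average_table",
    "orientation_summaries",
    "summary_matrix",
]

logger = logging.getLogger(__name__)

Statistic = Literal["mean", "median", "mmpd"]
STATISTICS: tuple[str, ...] = ("mean", "median", "mmpd")


def mmpd(values: Sequence[float] | np.ndarray) -> float:
    """Mean of the modal part of the distribution of ``values``.

    Values strictly above and strictly below 0.5 are counted; the side
    with the larger count is averaged together with any values exactly
    equal to 0.5.  On a tie (including the all-0.5 case) every value is
    averaged.

    Raises ``ValueError`` on an empty input or values outside [0, 1].
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("mmpd requires a non-empty list of values")
    if np.any((v < 0) | (v > 1)) or np.any(np.isnan(v)):
        raise ValueError("mmpd values must lie in [0, 1]")
    above = v > 0.5
    below = v < 0.5
    n_above = int(above.sum())
    n_below = int(below.sum())
    if n_above > n_below:
        keep = above | (v == 0.5)
    elif n_below > n_above:
        keep = below | (v == 0.5)
    else:
        if n_above > 0:  # genuine tie between the two sides
            logger.debug("mmpd tie (%d above, %d below): averaging all values",
                         n_above, n_below)
        keep = np.ones_like(v, dtype=bool)
    return float(v[keep].mean())


def incoherency(p_dangerous: float, p_harmless: float) -> float:
    """Incoherency index x = |p_D + p_H - 1| of a summarized preference pair."""
    for name, p in (("p_dangerous", p_dangerous), ("p_harmless", p_harmless)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} = {p} outside [0, 1]")
    return abs(p_dangerous + p_harmless - 1.0)


_SUMMARIZERS = {
    "mean": lambda v: float(np.mean(v)),
    "median": lambda v: float(np.median(v)),
    "mmpd": mmpd,
}


def summarize_preferences(cohort: CohortTable, statistic: Statistic = "mmpd",
                          ) -> pd.DataFrame:
    """One summary per (participant, feature, instruction).

    Trials are pooled across orientations.  Returns a tidy frame with
    columns ``participant_id, feature, instruction, statistic, value,
    n_trials``.  Participants lacking trials for an instruction are
    omitted from the affected cells with a warning.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    fn = _SUMMARIZERS[statistic]
    rows = []
    for (pid, instr), grp in cohort.trials.groupby(
            ["participant_id", "instruction"], sort=True):
        for f in FEATURES:
            rows.append({
                "participant_id": pid, "feature": f, "instruction": instr,
                "statistic": statistic, "value": fn(grp[f].to_numpy()),
                "n_trials": len(grp),
            })
    seen = {(pid, instr) for (pid, instr), _ in
            cohort.trials.groupby(["participant_id", "instruction"])}
    for pid in cohort.participants["participant_id"]:
        for instr in INSTRUCTIONS:
            if (pid, instr) not in seen:
                warnings.warn(
                    f"participant {pid!r} has no {instr} trials; summary omitted",
                    stacklevel=2,
                )
    return pd.DataFrame(rows, columns=["participant_id", "feature", "instruction",
                                       "statistic", "value", "n_trials"])


def incoherency_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, feature) incoherency from a summary frame.

    ``summaries`` must hold a single statistic.  Returns columns
    ``participant_id, feature, statistic, x``.
    """
    stats = summaries["statistic"].unique()
    if len(stats) != 1:
        raise ValueError("incoherency_table expects summaries of a single statistic")
    wide = summaries.pivot_table(index=["participant_id", "feature"],
                                 columns="instruction", values="value")
    if not {"dangerous", "harmless"} <= set(wide.columns):
        raise ValueError("summaries must cover both instructions")
    wide = wide.dropna(subset=["dangerous", "harmless"])
    out = wide.reset_index()
    out["statistic"] = stats[0]
    out["x"] = [incoherency(d, h) for d, h in zip(out["dangerous"], out["harmless"])]
    return out[["participant_id", "feature", "statistic", "x"]]


def grand_average_table(cohort: CohortTable,
                        incoherency_statistic: Statistic = "mmpd",
                        ) -> pd.DataFrame:
    """Grand averages (SD in brackets conceptually) across participants.

    Rows: the three summary statistics over the six (feature,
    instruction) cells, plus one incoherency row per feature computed
    from ``incoherency_statistic`` summaries.  Returns a tidy frame with
    columns ``statistic, feature, instruction, mean, sd, n`` where the
    incoherency row carries ``instruction = ""``.
    """
    rows = []
    per_stat: dict[str, pd.DataFrame] = {}
    for stat in STATISTICS:
        summ = summarize_preferences(cohort, stat)
        per_stat[stat] = summ
        g = summ.groupby(["feature", "instruction"])["value"]
        for (f, instr), vals in g:
            rows.append({"statistic": stat, "feature": f, "instruction": instr,
                         "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                         "n": int(vals.size)})
    inco = incoherency_table(per_stat[incoherency_statistic])
    for f, vals in inco.groupby("feature")["x"]:
        rows.append({"statistic": "incoherency", "feature": f, "instruction": "",
                     "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
                     "n": int(vals.size)})
    frame = pd.DataFrame(rows)
    order = {s: k for k, s in enumerate((*STATISTICS, "incoherency"))}
    frame = frame.sort_values(
        ["statistic", "feature", "instruction"],
        key=lambda c: c.map(order) if c.name == "statistic" else c,
    ).reset_index(drop=True)
    return frame


def orientation_summaries(cohort: CohortTable, statistic: Statistic = "mmpd",
                          ) -> pd.DataFrame:
    """Grand means stratified by spider orientation.

    The balanced design provides 4 trials per participant per
    (instruction, orientation) cell; the same per-participant summary is
    applied within each orientation stratum, then averaged across
    participants.  Columns: ``feature, instruction, orientation, mean,
    sd, n``.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")
    fn = _SUMMARIZERS[statistic]
    rows = []
    for (pid, instr, orient), grp in cohort.trials.groupby(
            ["participant_id", "instruction", "orientation"], sort=True):
        for f in FEATURES:
            rows.append({"participant_id": pid, "feature": f, "instruction": instr,
                         "orientation": orient, "value": fn(grp[f].to_numpy())})
    per = pd.DataFrame(rows)
    g = per.groupby(["feature", "instruction", "orientation"])["value"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    out["n"] = out["n"].astype(int)
    return out


def summary_matrix(cohort: CohortTable, statistic: Statistic = "mmpd",
                   ) -> pd.DataFrame:
    """Participants x variables matrix: SPQ plus the six preference summaries.

    Column order: ``spq, hairiness_dangerous, hairiness_harmless,
    bodyleg_dangerous, bodyleg_harmless, locomotion_dangerous,
    locomotion_harmless``; index is the participant id.  This is the
    input to the association and clustering stages.
    """
    summ = summarize_preferences(cohort, statistic)
    wide = summ.pivot_table(index="participant_id", columns=["feature", "instruction"],
                            values="value")
    wide.columns = [f"{f}_{i}" for f, i in wide.columns]
    ordered = [f"{f}_{i}" for f in FEATURES for i in INSTRUCTIONS]
    wide = wide.reindex(columns=ordered)
    spq = cohort.participants.set_index("participant_id")["spq"]
    wide.insert(0, "spq", spq.reindex(wide.index).astype(float))
    return wide
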