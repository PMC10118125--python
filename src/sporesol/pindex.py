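"""Detection filtering and the pellet-fraction solubility statistic.

The central statistic for a protein at one time point in one replicate
is ``pellet / (supernatant + pellet)``: 0 means the protein was found
only in the supernatant (fully soluble), 1 only in the pellet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "FilterReport",
    "apply_detection_filters",
    "compute_pindex",
    "pindex_long",
    "summarize_replicates",
    "phospho_relative_abundance",
]

REASON_LOW_COVERAGE = "low_coverage"
REASON_FEW_PEPTIDES = "few_peptides"
REASON_INCOMPLETE_SERIES = "incomplete_series"

# reason priority when a protein fails several criteria
_REASON_ORDER = (REASON_LOW_COVERAGE, REASON_FEW_PEPTIDES, REASON_INCOMPLETE_SERIES)


@dataclass
class FilterReport:
    """Outcome of the detection filters."""

    n_input_proteins: int
    n_pass: int
    exclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_pass + len(self.exclusions) == self.n_input_proteins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": list(self.exclusions), "reason": list(self.exclusions.values())}
        )


def compute_pindex(supernatant_abundance: float, pellet_abundance: float) -> float:
    """Pellet share of total abundance, in [0, 1].

    Raises
    ------
    ValidationError
        If either abundance is negative or both are zero (undetected
        proteins must be filtered out before calling).
    """
    s = float(supernatant_abundance)
    p = float(pellet_abundance)
    if s < 0 or p < 0:
        raise ValidationError("abundances must be non-negative")
    total = s + p
    if total <= 0:
        raise ValidationError("total abundance is zero; protein not detected")
    return p / total


def apply_detection_filters(
    table: pd.DataFrame,
    min_coverage: float = 0.10,
    min_peptides: int = 2,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep proteins that are confidently and completely detected.

    A protein is retained when (a) its sequence coverage reaches
    ``min_coverage``, (b) it has at least ``min_peptides`` peptides, and
    (c) supernatant + pellet abundance is strictly positive in every
    replicate at every time point present in the table.  Coverage and
    peptide count are evaluated on the per-protein maximum across runs
    (protein-level values as reported by search engines).  Missing
    abundance cells count as zero for criterion (c).
    """
    if table.shape[0] == 0:
        return table.copy(), FilterReport(0, 0, {})

    proteins = list(dict.fromkeys(table["protein_id"]))
    time_points = list(dict.fromkeys(table["time_point"].astype(str)))
    replicates = sorted(set(table["replicate"]))

    per_protein = table.groupby("protein_id", sort=False).agg(
        max_coverage=("coverage", "max"), max_peptides=("n_peptides", "max")
    )

    # total (sup + pellet) per protein x time x replicate; NaN -> 0
    totals = (
        table.assign(time_point=table["time_point"].astype(str))
        .pivot_table(
            index="protein_id",
            columns=["time_point", "replicate"],
            values="abundance",
            aggfunc="sum",
            fill_value=0.0,
            observed=True,
        )
        .reindex(proteins)
    )
    expected_cells = len(time_points) * len(replicates)

    exclusions: dict[str, str] = {}
    for pid in proteins:
        reasons = []
        if per_protein.loc[pid, "max_coverage"] < min_coverage:
            reasons.append(REASON_LOW_COVERAGE)
        if per_protein.loc[pid, "max_peptides"] < min_peptides:
            reasons.append(REASON_FEW_PEPTIDES)
        row = totals.loc[pid]
        if row.shape[0] < expected_cells or (row <= 0).any() or row.isna().any():
            reasons.append(REASON_INCOMPLETE_SERIES)
        if reasons:
            exclusions[pid] = min(reasons, key=_REASON_ORDER.index)

    kept = table[~table["protein_id"].isin(exclusions)].copy()
    report = FilterReport(
        n_input_proteins=len(proteins),
        n_pass=len(proteins) - len(exclusions),
        exclusions=exclusions,
    )
    return kept, report


def pindex_long(table: pd.DataFrame) -> pd.DataFrame:
    """Per protein x time x replicate solubility statistic (long form).

    Expects a filtered fraction-quant table (every cell detected).
    """
    wide = table.pivot_table(
        index=["protein_id", "time_point", "replicate"],
        columns="fraction",
        values="abundance",
        aggfunc="sum",
        observed=True,
    ).fillna(0.0)
    for frac in ("supernatant", "pellet"):
        if frac not in wide.columns:
            wide[frac] = 0.0
    total = wide["supernatant"] + wide["pellet"]
    if (total <= 0).any():
        bad = wide.index[total <= 0][0]
        raise ValidationError(f"zero total abundance for {bad}; run detection filters first")
    out = wide.reset_index()
    out["pindex"] = (wide["pellet"] / total).to_numpy()
    out = out[["protein_id", "time_point", "replicate", "pindex"]]
    # preserve original protein order
    order = {p: i for i, p in enumerate(dict.fromkeys(table["protein_id"]))}
    out = out.sort_values(
        by=["protein_id", "time_point", "replicate"],
        key=lambda s: s.map(order) if s.name == "protein_id" else s,
        kind="stable",
    ).reset_index(drop=True)
    return out


def summarize_replicates(
    records: pd.DataFrame,
    time_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean trajectory matrix and pairwise replicate correlations.

    Parameters
    ----------
    records
        Long-form table with columns ``protein_id``, ``time_point``,
        ``replicate``, ``pindex``.

    Returns
    -------
    mean_matrix
        proteins x time points, arithmetic mean over replicates, rows in
        first-appearance order.
    correlations
        One row per unordered replicate pair with the Pearson r computed
        over all protein x time cells shared by the pair (pairwise
        deletion of missing cells).
    """
    proteins = list(dict.fromkeys(records["protein_id"]))
    if time_order is None:
        time_order = list(dict.fromkeys(records["time_point"].astype(str)))
    cube = records.assign(time_point=records["time_point"].astype(str)).pivot_table(
        index="protein_id", columns=["time_point", "replicate"], values="pindex",
        observed=True,
    ).reindex(proteins)

    replicates = sorted(set(records["replicate"]))
    mean_matrix = pd.DataFrame(index=pd.Index(proteins, name="protein_id"))
    for tp in time_order:
        cols = [(tp, r) for r in replicates if (tp, r) in cube.columns]
        mean_matrix[tp] = cube[cols].mean(axis=1) if cols else np.nan

    rows = []
    if len(replicates) < 2:
        warnings.warn("single replicate: correlations empty", stacklevel=2)
    else:
        for i, ra in enumerate(replicates):
            for rb in replicates[i + 1:]:
                a = cube.loc[:, [(tp, ra) for tp in time_order if (tp, ra) in cube.columns]]
                b = cube.loc[:, [(tp, rb) for tp in time_order if (tp, rb) in cube.columns]]
                a.columns = [c[0] for c in a.columns]
                b.columns = [c[0] for c in b.columns]
                common = [c for c in a.columns if c in b.columns]
                av = a[common].to_numpy().ravel()
                bv = b[common].to_numpy().ravel()
                ok = ~(np.isnan(av) | np.isnan(bv))
                n = int(ok.sum())
                r = np.nan
                if n >= 2 and np.std(av[ok]) > 0 and np.std(bv[ok]) > 0:
                    r = float(np.corrcoef(av[ok], bv[ok])[0, 1])
                rows.append({"replicate_a": ra, "replicate_b": rb, "pearson_r": r, "n_cells": n})
    correlations = pd.DataFrame(rows, columns=["replicate_a", "replicate_b", "pearson_r", "n_cells"])
    return mean_matrix, correlations


def phospho_relative_abundance(
    phospho: pd.DataFrame,
    totals: pd.DataFrame,
) -> pd.DataFrame:
    """Phosphopeptide intensity relative to total protein abundance.

    ``totals`` is a proteins x time-points matrix of mean total
    (supernatant + pellet) abundance.  Intensities are first averaged
    over replicates per (protein, site, time), then divided by the mean
    total.  Sites on proteins absent from ``totals`` are dropped with a
    warning; time points with zero total get NaN and ``undefined=True``.
    """
    orphans = sorted(set(phospho["protein_id"]) - set(totals.index))
    if orphans:
        warnings.warn(f"{len(orphans)} phosphoprotein(s) missing from totals: {orphans[:5]}",
                      stacklevel=2)
    kept = phospho[~phospho["protein_id"].isin(orphans)]
    mean_int = (
        kept.assign(time_point=kept["time_point"].astype(str))
        .groupby(["protein_id", "site_label", "time_point"], sort=False, observed=True)["intensity"]
        .mean()
        .reset_index()
    )
    rows = []
    for _, rec in mean_int.iterrows():
        tp = rec["time_point"]
        if tp not in totals.columns:
            raise ValidationError(f"time point {tp!r} absent from totals")
        total = totals.at[rec["protein_id"], tp]
        undefined = not (total and total > 0 and not np.isnan(total))
        rows.append(
            {
                "protein_id": rec["protein_id"],
                "site_label": rec["site_label"],
                "time_point": tp,
                "relative_abundance": np.nan if undefined else rec["intensity"] / total,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "site_label", "time_point", "relative_abundance", "undefined"],
    )
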