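"""Metabolite-table statistics: normalization, dysregulation calls, enrichment.

The pipeline starts from a peak-area table (samples × metabolites, arbitrary
units). Each sample is first normalized by its total ion current (TIC, the
sum of all recorded peaks), then each metabolite by its control-group mean.
Dysregulation is called per metabolite with a one-way ANOVA across
genotypes, gated on both the raw ANOVA p-value and the table-wide
Benjamini–Hochberg q-value; called metabolites are segregated to the mutant
lines in which Fisher's LSD against control is significant, with direction
taken from the control-relative mean. Enrichment of a hit list against a
metabolite-set library is the hypergeometric over-representation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import robust_stats
from .errors import ConfigurationError, InvalidParameterError

NormalizationState = Literal["raw", "tic", "control-relative"]


@dataclass
class MetaboliteTable:
    """Peak areas for samples × metabolites with per-sample group labels."""

    values: pd.DataFrame  # index: sample ids, columns: metabolite names
    groups: pd.Series  # sample id -> group label
    normalization_state: NormalizationState = "raw"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.groups = pd.Series(self.groups).reindex(self.values.index)
        if self.groups.isna().any():
            missing = list(self.values.index[self.groups.isna()])
            raise ConfigurationError(f"samples without group labels: {missing}")
        if (self.values.values < 0).any() or not np.isfinite(self.values.values).all():
            raise InvalidParameterError("peak areas must be non-negative and finite")

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def group_values(self, metabolite: str) -> dict[str, np.ndarray]:
        col = self.values[metabolite]
        return {g: col[self.groups == g].to_numpy() for g in self.group_names}

    @classmethod
    def from_csv(cls, path: str | Path) -> "MetaboliteTable":
        """Read the CSV layout: sample id, group, then one column per metabolite."""
        df = pd.read_csv(path)
        sample_col, group_col = df.columns[:2]
        values = df.set_index(sample_col).drop(columns=[group_col])
        groups = df.set_index(sample_col)[group_col]
        return cls(values=values, groups=groups)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.index.name = "sample"
        out.to_csv(path)


@dataclass
class DysregulationCall:
    """One metabolite passing the joint p/q dysregulation gate."""

    metabolite: str
    groups_affected: list[str]
    p_anova: float
    q_value: float
    direction: dict[str, str] = field(default_factory=dict)  # group -> "up"|"down"


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one metabolite set."""

    set_name: str
    set_size: int
    n_hits: int
    overlap: int
    p_hypergeometric: float
    q_value: float = float("nan")


def tic_normalize(table: MetaboliteTable) -> MetaboliteTable:
    """Divide each sample by its total ion current (row sum).

    Idempotent: rows already summing to one are unchanged. A zero-total
    sample cannot be normalized and is dropped with a warning.
    """
    totals = table.values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        dropped = list(table.values.index[zero])
        warnings.warn(f"dropping zero-total samples: {dropped}", stacklevel=2)
    values = table.values.loc[~zero].div(totals[~zero], axis=0)
    return MetaboliteTable(values, table.groups.loc[~zero], "tic")


def normalize_to_control(table: MetaboliteTable, control_group: str) -> MetaboliteTable:
    """Divide each metabolite by its control-group mean (control maps to 1).

    Metabolites whose control mean is zero are excluded with a warning.
    """
    if control_group not in set(table.groups):
        raise ConfigurationError(f"control group {control_group!r} not present")
    ctrl = table.values[table.groups == control_group].mean(axis=0)
    bad = ctrl <= 0
    if bad.any():
        warnings.warn(
            f"excluding metabolites with zero control mean: {list(ctrl.index[bad])}",
            stacklevel=2,
        )
    values = table.values.loc[:, ~bad].div(ctrl[~bad], axis=1)
    return MetaboliteTable(values, table.groups, "control-relative")


def call_dysregulated(
    table: MetaboliteTable,
    control_group: str,
    alpha: float = 0.05,
    q: float = 0.01,
) -> tuple[list[DysregulationCall], pd.DataFrame]:
    """Call dysregulated metabolites and segregate them by affected line.

    Per metabolite a one-way ANOVA is run across all genotype groups; BH-FDR
    is applied table-wide. A metabolite is called when its raw ANOVA p-value
    is below ``alpha`` AND its q-value is at most ``q`` (both gates are
    recorded in the returned per-metabolite frame). For each called
    metabolite, the affected lines are those mutants whose Fisher's LSD
    contrast against control is significant at ``alpha``, with direction
    from the sign of the control-relative mean difference.

    Returns ``(calls, per_metabolite)`` where ``per_metabolite`` holds the
    full statistics for every metabolite, called or not.
    """
    if alpha < 0 or not (0 <= q <= 1):
        raise InvalidParameterError("alpha must be >= 0 and q in [0, 1]")
    if control_group not in set(table.groups):
        raise ConfigurationError(f"control group {control_group!r} not present")

    metabolites = table.metabolites
    pvals = np.empty(len(metabolites))
    anovas = []
    for j, m in enumerate(metabolites):
        res = robust_stats.oneway_anova(table.group_values(m))
        anovas.append(res)
        pvals[j] = res.p_anova
    _, qvals = robust_stats.bh_fdr(pvals, q)
    called = (pvals < alpha) & (qvals <= q)

    mutants = [g for g in table.group_names if g != control_group]
    calls: list[DysregulationCall] = []
    rows = []
    for j, m in enumerate(metabolites):
        rows.append(
            {
                "metabolite": m,
                "p_anova": pvals[j],
                "q_value": qvals[j],
                "called": bool(called[j]),
            }
        )
        if not called[j]:
            continue
        lsd = robust_stats.fishers_lsd(table.group_values(m), control=control_group)
        affected = []
        direction = {}
        for comp in lsd.comparisons:
            if comp.p_unadjusted < alpha:
                affected.append(comp.group)
                direction[comp.group] = "up" if comp.estimate > 0 else "down"
        calls.append(
            DysregulationCall(
                metabolite=m,
                groups_affected=affected,
                p_anova=float(pvals[j]),
                q_value=float(qvals[j]),
                direction=direction,
            )
        )
    per_metabolite = pd.DataFrame(rows)
    return calls, per_metabolite


def ora_enrichment(
    hits: Sequence[str],
    library: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    q: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of ``hits`` in each library set (upper-tail
    hypergeometric), with BH-FDR across sets.

    Library sets are intersected with the measured universe before testing;
    hits must be a subset of the universe.
    """
    uni = set(universe)
    hit_set = set(hits)
    if not uni or not hit_set:
        warnings.warn("empty universe or hit list: no enrichment computed", stacklevel=2)
        return []
    if not hit_set <= uni:
        raise ConfigurationError("hits must be a subset of the universe")
    M, N = len(uni), len(hit_set)
    results = []
    for name, members in library.items():
        in_uni = set(members) & uni
        n = len(in_uni)
        k = len(in_uni & hit_set)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        results.append(EnrichmentResult(name, n, N, k, min(p, 1.0)))
    _, qvals = robust_stats.bh_fdr([r.p_hypergeometric for r in results], q)
    return [replace(r, q_value=float(qv)) for r, qv in zip(results, qvals)]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT-style metabolite-set library: name, description, members."""
    library: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"malformed GMT line: {line!r}")
        library[parts[0]] = [m for m in parts[2:] if m]
    return library
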