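"""Two-group expression comparison -> directional State Changes.

A State Change (SC) is a gene whose expression differs significantly between
treatment and control: BH-adjusted p below a cutoff and linear fold change
above a cutoff, with an optional mean-intensity floor.  Genes measured by
several probe sets change if at least one probe set changes; the direction is
taken from the passing probes.

The pipeline is: quantile normalization -> per-probe pooled-variance
two-group t-test on log2 intensities -> Benjamini-Hochberg adjustment ->
threshold filter chain -> gene-level collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, TextIO

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ComparisonDesign",
    "StateChange",
    "StateChangeSet",
    "quantile_normalize",
    "differential_test",
    "bh_adjust",
    "call_state_changes",
    "run_state_change_pipeline",
    "read_expression_tsv",
    "read_design_tsv",
    "read_probe_map_tsv",
    "write_state_changes_tsv",
    "read_state_changes_tsv",
]


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity matrix with an explicit scale flag.

    ``values`` is a DataFrame indexed by probe id with sample-id columns.
    Linear-scale values must be finite and non-negative.
    """

    values: pd.DataFrame
    log2: bool = False

    def __post_init__(self):
        v = self.values
        if v.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if v.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if not self.log2 and (arr < 0).any():
            raise ValueError("linear-scale intensities must be non-negative")

    def to_log2(self) -> "ExpressionMatrix":
        if self.log2:
            return self
        return ExpressionMatrix(np.log2(self.values + 1.0), log2=True)

    def to_linear(self) -> "ExpressionMatrix":
        if not self.log2:
            return self
        return ExpressionMatrix(np.exp2(self.values), log2=False)


@dataclass
class ComparisonDesign:
    """One two-group contrast: disjoint treatment and control sample sets."""

    label: str
    treatment_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self):
        t, c = set(self.treatment_samples), set(self.control_samples)
        if t & c:
            raise ValueError("treatment and control samples overlap")
        if len(t) < 2 or len(c) < 2:
            raise ValueError("each group needs at least 2 samples")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        missing = (set(self.treatment_samples) | set(self.control_samples)) \
            - set(matrix.values.columns)
        if missing:
            raise ValueError(f"samples missing from matrix: {sorted(missing)}")


@dataclass(frozen=True)
class StateChange:
    gene: str
    direction: str  # "increased" | "decreased"
    fold_change: float  # linear ratio >= 1; direction carries the sign
    adjusted_p: float

    def __post_init__(self):
        if self.direction not in ("increased", "decreased"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def sign(self) -> int:
        return +1 if self.direction == "increased" else -1


@dataclass
class StateChangeSet:
    """Directional significant changes for one comparison, with the measured
    gene population they were drawn from."""

    label: str
    population: frozenset[str]
    changes: list[StateChange] = field(default_factory=list)

    def __post_init__(self):
        self.population = frozenset(self.population)
        genes = [c.gene for c in self.changes]
        if len(genes) != len(set(genes)):
            raise ValueError("at most one state change per gene")
        stray = set(genes) - self.population
        if stray:
            raise ValueError(f"state-change genes outside population: {sorted(stray)}")

    @property
    def directions(self) -> dict[str, int]:
        return {c.gene: c.sign for c in self.changes}

    def __len__(self) -> int:
        return len(self.changes)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of row-wise means of
    the column-sorted data; ties within a column share the average of the
    reference values at their ranks.  Idempotent."""
    df = matrix.values
    arr = df.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties avg
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), ref)
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns),
                            log2=matrix.log2)


def differential_test(matrix: ExpressionMatrix,
                      design: ComparisonDesign) -> pd.DataFrame:
    """Per-probe two-group comparison.

    Returns a DataFrame indexed by probe with columns ``log2_fc`` (mean log2
    treatment minus mean log2 control), ``mean_intensity`` (linear scale,
    over both groups) and ``raw_p`` (pooled-variance equal-variance t-test).
    """
    design.validate_against(matrix)
    log2m = matrix.to_log2().values
    lin = matrix.to_linear().values
    t_cols = list(design.treatment_samples)
    c_cols = list(design.control_samples)
    tvals = log2m[t_cols].to_numpy(dtype=float)
    cvals = log2m[c_cols].to_numpy(dtype=float)
    if np.allclose(tvals.var(axis=1, ddof=1), 0) and \
       np.allclose(cvals.var(axis=1, ddof=1), 0):
        raise ValueError(
            "zero within-group variance for every probe; add replicates or jitter")
    import warnings
    with warnings.catch_warnings():
        # near-constant probes trigger a scipy precision warning; their
        # p-values are treated as 1 below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, raw_p = stats.ttest_ind(tvals, cvals, axis=1, equal_var=True)
    log2_fc = tvals.mean(axis=1) - cvals.mean(axis=1)
    mean_intensity = lin[t_cols + c_cols].to_numpy(dtype=float).mean(axis=1)
    # degenerate probes (zero pooled variance) give nan p; treat as p = 1
    raw_p = np.where(np.isnan(raw_p), 1.0, raw_p)
    return pd.DataFrame(
        {"log2_fc": log2_fc, "mean_intensity": mean_intensity, "raw_p": raw_p},
        index=matrix.values.index)


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_state_changes(results: pd.DataFrame,
                       probe_map: Mapping[str, str],
                       label: str = "comparison",
                       adj_p: float = 0.05,
                       fc: float = 1.3,
                       min_intensity: float | None = None) -> StateChangeSet:
    """Apply the filter chain and collapse probes to gene-level State Changes.

    A probe passes iff adjusted_p < ``adj_p`` AND linear |FC| > ``fc`` AND
    (``min_intensity`` is None OR mean_intensity > ``min_intensity``); all
    inequalities strict.  A gene changes if at least one of its probes
    passes; genes whose passing probes disagree in direction are dropped from
    the change list (but stay in the population).  The population is every
    mapped gene with at least one measured probe and does not depend on the
    thresholds.
    """
    if adj_p <= 0 or fc <= 1:
        raise ValueError("thresholds must be positive with fc > 1")
    res = results.copy()
    if "adjusted_p" not in res.columns:
        res["adjusted_p"] = bh_adjust(res["raw_p"].to_numpy())
    res = res.loc[[p for p in res.index if p in probe_map]]
    genes = pd.Series({p: probe_map[p] for p in res.index}, name="gene")
    population = frozenset(genes)

    linear_fc = np.exp2(np.abs(res["log2_fc"].to_numpy()))
    passes = (res["adjusted_p"].to_numpy() < adj_p) & (linear_fc > fc)
    if min_intensity is not None:
        passes &= res["mean_intensity"].to_numpy() > min_intensity

    changes: list[StateChange] = []
    passing = res.loc[passes]
    for gene, sub in passing.groupby(genes.loc[passing.index]):
        signs = set(np.sign(sub["log2_fc"]).astype(int))
        if signs == {+1} or signs == {-1}:
            best = sub.loc[sub["adjusted_p"].idxmin()]
            direction = "increased" if best["log2_fc"] > 0 else "decreased"
            changes.append(StateChange(
                gene=str(gene), direction=direction,
                fold_change=float(np.exp2(abs(best["log2_fc"]))),
                adjusted_p=float(best["adjusted_p"])))
        # conflicting directions: dropped, remains in population
    changes.sort(key=lambda c: c.gene)
    return StateChangeSet(label=label, population=population, changes=changes)


def run_state_change_pipeline(matrix: ExpressionMatrix,
                              design: ComparisonDesign,
                              probe_map: Mapping[str, str],
                              adj_p: float = 0.05,
                              fc: float = 1.3,
                              min_intensity: float | None = None,
                              normalize: bool = True) -> StateChangeSet:
    """Quantile-normalize, test, adjust and call in one step."""
    if normalize:
        matrix = quantile_normalize(matrix)
    res = differential_test(matrix, design)
    res["adjusted_p"] = bh_adjust(res["raw_p"].to_numpy())
    return call_state_changes(res, probe_map, label=design.label,
                              adj_p=adj_p, fc=fc, min_intensity=min_intensity)


# ---------------------------------------------------------------------------
# plain-text I/O

def read_expression_tsv(stream: TextIO, log2: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(stream, sep="\t", index_col=0)
    return ExpressionMatrix(df, log2=log2)


def read_design_tsv(stream: TextIO, treatment: str, control: str,
                    label: str | None = None) -> ComparisonDesign:
    """Read a two-column ``sample_id<TAB>group`` file and build the contrast
    ``treatment`` vs ``control``."""
    df = pd.read_csv(stream, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    groups = df.groupby("group")["sample_id"].apply(tuple).to_dict()
    for g in (treatment, control):
        if g not in groups:
            raise ValueError(f"group {g!r} not in design file")
    return ComparisonDesign(label or f"{treatment}_vs_{control}",
                            groups[treatment], groups[control])


def read_probe_map_tsv(stream: TextIO) -> dict[str, str]:
    df = pd.read_csv(stream, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    mapping = {}
    for probe, gene in zip(df["probe_id"], df["gene_symbol"]):
        if isinstance(gene, str) and gene.strip():
            mapping[probe] = gene.strip()
    return mapping


def write_state_changes_tsv(scs: StateChangeSet, stream: TextIO) -> None:
    stream.write("gene\tdirection\tfold_change\tadjusted_p\n")
    for c in scs.changes:
        stream.write(f"{c.gene}\t{c.direction}\t{c.fold_change:.6g}\t{c.adjusted_p:.6g}\n")


def read_state_changes_tsv(stream: TextIO, population: frozenset[str],
                           label: str = "comparison") -> StateChangeSet:
    df = pd.read_csv(stream, sep="\t", dtype={"gene": str})
    changes = [StateChange(r.gene, r.direction, float(r.fold_change),
                           float(r.adjusted_p))
               for r in df.itertuples()]
    return StateChangeSet(label=label, population=population, changes=changes)
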