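"""Taxon count-table front end: preprocessing, BMI grouping, taxon selection.

Microbiome abundance tables are zero-inflated and correlated, so before any
model fit the pipeline (optionally) converts counts to per-sample relative
abundances, replaces zeros by half the minimum observed positive abundance
— the standard pseudo-count convention — and applies a natural-log
transform.  Obesity phenotypes are encoded from BMI with the conventional
cut points (underweight < 18.5, normal [18.5, 25), overweight [25, 30),
obese >= 30 kg/m^2), and the binary outcome is obese vs not within a chosen
grouping of BMI classes.

Because the real cohort data are not shipped, ``generate_synthetic_counts``
produces a synthetic stand-in with the same qualitative features
(correlated log-abundances, a target zero fraction, a sparse logistic
association with obesity) and a known set of truly associated taxa, so the
whole pipeline can be exercised and its error control measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.special import expit

from .aggregation import AggregationResult, aggregate_knockoffs
from .selection import select

__all__ = [
    "CountTable",
    "PhenotypeTable",
    "GROUPINGS",
    "bmi_group",
    "preprocess_counts",
    "build_grouping",
    "select_taxa",
    "generate_synthetic_counts",
]

BMI_CUTS = {"uw": (0.0, 18.5), "nor": (18.5, 25.0), "ow": (25.0, 30.0),
            "ob": (30.0, np.inf)}

GROUPINGS = ("all", "uw+ob", "nor+ob", "ow+ob", "uw+nor+ob", "uw+ow+ob",
             "nor+ow+ob")


@dataclass(frozen=True)
class CountTable:
    """Samples-by-taxa abundance matrix with labels.

    ``counts`` holds raw counts or relative abundances (all entries >= 0);
    rows are samples, columns are taxa.
    """

    counts: NDArray
    taxon_names: list[str]
    sample_ids: list[str]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D samples-by-taxa matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.taxon_names) != counts.shape[1]:
            raise ValueError("taxon_names length must match the number of columns")
        if len(self.sample_ids) != counts.shape[0]:
            raise ValueError("sample_ids length must match the number of rows")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise ValueError("taxon names must be unique")

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "CountTable":
        """Read a table with sample IDs in the first column, taxa as headers."""
        df = pd.read_csv(path, sep=sep, engine="python", index_col=0)
        if df.empty or df.shape[1] == 0:
            raise ValueError(f"count table {path} has no taxon columns")
        try:
            counts = df.to_numpy(dtype=float)
        except ValueError as err:
            raise ValueError(f"non-numeric entries in count table {path}: {err}") from err
        return cls(counts=counts, taxon_names=[str(c) for c in df.columns],
                   sample_ids=[str(i) for i in df.index])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.taxon_names)


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sample BMI (kg/m^2) with the derived weight-class labels."""

    sample_ids: list[str]
    bmi: NDArray

    def __post_init__(self):
        bmi = np.asarray(self.bmi, dtype=float)
        object.__setattr__(self, "bmi", bmi)
        if len(self.sample_ids) != bmi.size:
            raise ValueError("sample_ids and bmi lengths differ")
        if np.any(bmi <= 0) or not np.all(np.isfinite(bmi)):
            raise ValueError("BMI values must be positive and finite")

    @property
    def group(self) -> NDArray:
        return bmi_group(self.bmi)

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "PhenotypeTable":
        df = pd.read_csv(path, sep=sep, engine="python")
        cols = {c.lower(): c for c in df.columns}
        if "sample_id" not in cols or "bmi" not in cols:
            raise ValueError(
                f"phenotype table {path} needs 'sample_id' and 'bmi' columns, "
                f"found {list(df.columns)}"
            )
        return cls(sample_ids=[str(s) for s in df[cols["sample_id"]]],
                   bmi=df[cols["bmi"]].to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "bmi": self.bmi,
                             "group": self.group})


def bmi_group(bmi: NDArray) -> NDArray:
    """Weight class per BMI: uw < 18.5 <= nor < 25 <= ow < 30 <= ob."""
    bmi = np.asarray(bmi, dtype=float)
    out = np.empty(bmi.shape, dtype=object)
    out[bmi < 18.5] = "uw"
    out[(bmi >= 18.5) & (bmi < 25.0)] = "nor"
    out[(bmi >= 25.0) & (bmi < 30.0)] = "ow"
    out[bmi >= 30.0] = "ob"
    return out.astype(str)


def preprocess_counts(
    table: CountTable,
    pseudo_mode: str = "global_min",
    relative_abundance: bool = True,
) -> NDArray:
    """Zero replacement and log transform of an abundance table.

    Counts are optionally converted to per-sample relative abundances, zeros
    are replaced by 0.5 times the minimum observed positive abundance
    (globally by default, per taxon with ``pseudo_mode="per_taxon_min"``),
    and the natural log is taken entrywise.  The output is finite
    everywhere.  This is a single-shot transform: callers must not apply it
    twice.
    """
    mat = np.asarray(table.counts, dtype=float)
    if relative_abundance:
        totals = mat.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            bad = [table.sample_ids[i] for i in np.flatnonzero(totals.ravel() == 0)]
            raise ValueError(f"samples with all-zero counts: {bad}")
        mat = mat / totals
    if pseudo_mode == "global_min":
        positive = mat[mat > 0]
        if positive.size == 0:
            raise ValueError("table has no positive entries")
        mat = np.where(mat == 0, 0.5 * positive.min(), mat)
    elif pseudo_mode == "per_taxon_min":
        out = mat.copy()
        for j in range(mat.shape[1]):
            col = mat[:, j]
            pos = col[col > 0]
            if pos.size == 0:
                raise ValueError(
                    f"taxon {table.taxon_names[j]!r} is all-zero; drop it before "
                    "per-taxon zero replacement"
                )
            out[:, j] = np.where(col == 0, 0.5 * pos.min(), col)
        mat = out
    else:
        raise ValueError(f"unknown pseudo_mode {pseudo_mode!r}")
    return np.log(mat)


def build_grouping(pheno: PhenotypeTable, grouping: str) -> tuple[NDArray, NDArray]:
    """Samples belonging to a BMI grouping and the obese-vs-not outcome.

    Returns ``(row_indices, y)`` where y_i = 1 iff the sample is obese
    (BMI >= 30).  A grouping whose retained samples are single-class is an
    error.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; valid options: {GROUPINGS}")
    groups = pheno.group
    wanted = {"uw", "nor", "ow", "ob"} if grouping == "all" else set(grouping.split("+"))
    rows = np.flatnonzero(np.isin(groups, sorted(wanted)))
    y = (groups[rows] == "ob").astype(float)
    if rows.size == 0 or y.min() == y.max():
        raise ValueError(
            f"grouping {grouping!r} yields a single outcome class "
            f"({rows.size} samples); selection needs both classes"
        )
    return rows, y


@dataclass(frozen=True)
class TaxonSelectionReport:
    """Side-by-side KO / AKO taxon selections at one target level."""

    table: pd.DataFrame  # columns: taxon, selected_by_KO, selected_by_AKO, q
    grouping: str
    aggregation: AggregationResult
    n_samples: int

    def selected_taxa(self, method: str = "AKO") -> list[str]:
        col = f"selected_by_{method}"
        return self.table.loc[self.table[col], "taxon"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def select_taxa(
    table: CountTable,
    pheno: PhenotypeTable,
    grouping: str = "all",
    q: float = 0.1,
    k: int = 5,
    plus: bool = True,
    seed: int = 0,
    mode: str = "geometric",
    pseudo_mode: str = "global_min",
    relative_abundance: bool = True,
    n_grid: int = 50,
) -> TaxonSelectionReport:
    """Full pipeline: preprocess, group, and select obesity-associated taxa.

    Runs preprocessing, restricts to the grouping's samples, standardizes
    columns, estimates a shrinkage covariance, and applies the aggregated
    knockoff filter with the l1-logistic path statistic.  The report lists,
    per taxon, whether the single-run filter (KO, the first run thresholded
    at the full level q) and the aggregated filter (AKO) selected it.
    """
    if table.counts.shape[1] < 2:
        raise ValueError("need at least 2 taxa for selection")
    ids = {s: i for i, s in enumerate(table.sample_ids)}
    missing = [s for s in pheno.sample_ids if s not in ids]
    if missing:
        raise ValueError(f"phenotype samples missing from the count table: {missing[:5]}")
    order = np.array([ids[s] for s in pheno.sample_ids])
    logged = preprocess_counts(table, pseudo_mode=pseudo_mode,
                               relative_abundance=relative_abundance)[order]
    rows, y = build_grouping(pheno, grouping)
    Xg = logged[rows]
    sd = Xg.std(axis=0, ddof=0)
    if np.any(sd == 0):
        keep = sd > 0
        Xg, sd = Xg[:, keep], sd[keep]
        names = [t for t, k_ in zip(table.taxon_names, keep) if k_]
    else:
        names = list(table.taxon_names)
    if Xg.shape[1] < 2:
        raise ValueError("fewer than 2 taxa remain after dropping constant columns")
    X = (Xg - Xg.mean(axis=0)) / sd
    agg = aggregate_knockoffs(X, y, sigma="estimate", q=q, k=k, loss="logistic",
                              plus=plus, mode=mode, seed=seed, n_grid=n_grid)
    ko = select(agg.statistics[0].W, q, plus=plus)
    ako_set, ko_set = agg.union_set(), ko.selected_set()
    report = pd.DataFrame({
        "taxon": names,
        "selected_by_KO": [j in ko_set for j in range(len(names))],
        "selected_by_AKO": [j in ako_set for j in range(len(names))],
        "q": q,
    })
    return TaxonSelectionReport(table=report, grouping=grouping, aggregation=agg,
                                n_samples=int(rows.size))


def generate_synthetic_counts(
    n: int = 200,
    p: int = 50,
    n_signal: int = 5,
    zero_fraction: float = 0.3,
    rho: float = 0.5,
    effect_size: float = 2.0,
    seed: int = 0,
) -> tuple[CountTable, PhenotypeTable, NDArray]:
    """Synthetic zero-inflated count table with a known obesity signal.

    Latent log-abundances are drawn from N(0, Sigma_AR1(rho)), shifted and
    exponentiated to counts, and thinned to the target zero fraction by
    zeroing the smallest entries.  Obesity labels follow a logistic model on
    the standardized preprocessed signal taxa with slope
    ``effect_size / sqrt(n_signal)`` per taxon; BMI values are then drawn
    uniformly within the weight class consistent with each label.

    Returns ``(CountTable, PhenotypeTable, support)`` where ``support`` holds
    the 0-based indices of the truly associated taxa.  Synthetic stand-in for
    a real cohort table; no real data involved.
    """
    if not 0.0 <= zero_fraction < 1.0:
        raise ValueError("zero_fraction must lie in [0, 1)")
    if n_signal > p:
        raise ValueError("n_signal exceeds p")
    rng = np.random.default_rng(seed)
    idx = np.arange(p)
    chol = np.linalg.cholesky(rho ** np.abs(idx[:, None] - idx[None, :]))
    latent = rng.standard_normal((n, p)) @ chol.T
    counts = np.round(np.exp(latent + 3.0))
    n_zero = int(round(zero_fraction * counts.size))
    if n_zero > 0:
        flat = counts.ravel().copy()
        cut = np.argpartition(flat, n_zero - 1)[:n_zero]
        flat[cut] = 0.0
        counts = flat.reshape(counts.shape)
    taxa = [f"taxon_{j:03d}" for j in range(p)]
    samples = [f"S{i:04d}" for i in range(n)]
    table = CountTable(counts=counts, taxon_names=taxa, sample_ids=samples)
    support = np.sort(rng.choice(p, size=n_signal, replace=False))
    logged = preprocess_counts(table)
    Zs = logged[:, support]
    Zs = (Zs - Zs.mean(axis=0)) / Zs.std(axis=0)
    eta = (effect_size / np.sqrt(max(n_signal, 1))) * Zs.sum(axis=1)
    obese = rng.random(n) < expit(eta)
    bmi = np.empty(n)
    bmi[obese] = rng.uniform(30.0, 40.0, size=int(obese.sum()))
    lean_class = rng.choice(3, size=int((~obese).sum()), p=(0.1, 0.6, 0.3))
    lo = np.array([16.0, 18.5, 25.0])[lean_class]
    hi = np.array([18.5, 25.0, 30.0])[lean_class]
    bmi[~obese] = rng.uniform(lo, hi)
    pheno = PhenotypeTable(sample_ids=samples, bmi=bmi)
    return table, pheno, support
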