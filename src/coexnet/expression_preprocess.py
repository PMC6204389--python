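"""Count preprocessing: CPM filtering, TMM normalisation, RPKM, fold-change DE.

The pipeline order follows standard RNA-seq practice for network input
preparation: low-abundance genes are removed on raw CPM (counts per million
on raw library sizes), between-sample composition bias is corrected with the
trimmed mean of M-values (TMM), expression is reported as RPKM on the
TMM-effective library sizes, and differential expression against the control
condition is a pure two-fold-change rule on normalised condition means with a
small pseudocount guarding zero denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "ExprMatrix",
    "DEResult",
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "rpkm",
    "call_de",
]


@dataclass
class CountMatrix:
    """Raw gene-level counts with gene lengths and sample metadata.

    ``counts`` is genes x samples (nonnegative integers); ``gene_lengths`` is
    bp per gene; ``sample_meta`` is indexed by sample with columns
    ``condition``, ``timepoint``, ``replicate``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValueError(f"genes without length: {list(missing[:5])}")
        if (self.gene_lengths.loc[self.counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if not self.counts.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[genes],
            gene_lengths=self.gene_lengths.loc[genes],
            sample_meta=self.sample_meta,
        )

    def write_tsvs(self, directory: str | Path, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(directory / f"{prefix}counts.tsv", sep="\t",
                           index_label="gene")
        self.gene_lengths.rename("length").to_csv(
            directory / f"{prefix}gene_lengths.tsv", sep="\t", index_label="gene")
        self.sample_meta.to_csv(directory / f"{prefix}sample_meta.tsv", sep="\t",
                                index_label="sample")

    @classmethod
    def read_tsvs(cls, counts_path, lengths_path, meta_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts=counts, gene_lengths=lengths, sample_meta=meta)


@dataclass
class ExprMatrix:
    """Normalised expression (CPM or RPKM) with the TMM factors that made it."""

    values: pd.DataFrame
    norm_factors: pd.Series
    unit: str = "RPKM"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DEResult:
    """Fold-change DE calls per substrate time point plus an overall status."""

    log2fc: pd.DataFrame  # genes x timepoints
    status: pd.DataFrame  # genes x timepoints, values in {up, down, none}
    overall_status: pd.Series  # gene -> {up, down, mixed, none}

    def genes_with_status(self, status: str) -> list[str]:
        return list(self.overall_status.index[self.overall_status == status])

    def to_table(self) -> pd.DataFrame:
        rows = []
        for tp in self.log2fc.columns:
            part = pd.DataFrame({
                "gene": self.log2fc.index,
                "timepoint": tp,
                "log2fc": self.log2fc[tp].to_numpy(),
                "status": self.status[tp].to_numpy(),
            })
            rows.append(part)
        table = pd.concat(rows, ignore_index=True)
        table["overall_status"] = self.overall_status.loc[table["gene"]].to_numpy()
        return table


def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million on raw library sizes."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero)}")
    return mat / (lib / 1e6)


def filter_low_expression(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples."""
    if min_samples > counts.counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    c = cpm(counts)
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    return counts.subset_genes(counts.counts.index[keep])


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed-mean-of-M-values factor of one sample against the reference.

    Genes with a zero count in either sample are excluded; the remaining
    log2 ratios (M) are trimmed 30% on M and 5% on absolute intensity (A),
    and averaged with inverse asymptotic binomial-variance weights.
    """
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise ValueError("no genes expressed in both sample and reference")
    o = obs[mask].astype(float)
    r = ref[mask].astype(float)
    log_r = np.log2((o / lib_obs) / (r / lib_ref))
    abs_e = 0.5 * (np.log2(o / lib_obs) + np.log2(r / lib_ref))
    var = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / var[keep]) / np.sum(1.0 / var[keep])
    return float(2.0 ** f)


def tmm_factors(counts: CountMatrix, reference: str | None = None) -> pd.Series:
    """Per-sample TMM normalisation factors, rescaled to geometric mean 1.

    The reference sample (when not given) is the one whose upper-quartile of
    library-size-scaled counts is closest to the mean upper quartile.
    """
    mat = counts.counts
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = mat.sum(axis=0).astype(float)
    if reference is None:
        uq = (mat / lib).quantile(0.75, axis=0)
        reference = (uq - uq.mean()).abs().idxmin()
    elif reference not in mat.columns:
        raise ValueError(f"unknown reference sample {reference!r}")
    ref = mat[reference].to_numpy()
    factors = {}
    for s in mat.columns:
        if s == reference:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_pair(mat[s].to_numpy(), ref, lib[s], lib[reference])
    f = pd.Series(factors, name="tmm_factor").loc[mat.columns]
    f = f / np.exp(np.mean(np.log(f)))
    return f


def rpkm(counts: CountMatrix, factors: pd.Series | None = None) -> ExprMatrix:
    """Reads per kilobase per million on TMM-effective library sizes."""
    mat = counts.counts
    missing = mat.index.difference(counts.gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length for: {list(missing[:5])}")
    if factors is None:
        factors = pd.Series(1.0, index=mat.columns)
    if (factors <= 0).any():
        raise ValueError("TMM factors must be positive")
    eff_lib = mat.sum(axis=0) * factors.loc[mat.columns]
    kb = counts.gene_lengths.loc[mat.index] / 1e3
    values = mat / (eff_lib / 1e6)
    values = values.div(kb, axis=0)
    return ExprMatrix(values=values, norm_factors=factors, unit="RPKM")


def call_de(
    expr: ExprMatrix,
    sample_meta: pd.DataFrame,
    control: str,
    pseudo: float = 0.25,
    lfc_threshold: float = 1.0,
) -> DEResult:
    """Two-fold-change DE calls of each substrate time point vs the control.

    ``log2fc(g, t) = log2((mean_t + pseudo) / (mean_control + pseudo))`` on
    normalised expression; a gene is up at t if log2fc >= ``lfc_threshold``
    and down if <= -``lfc_threshold``.  The overall status is up/down if any
    time point qualifies, and mixed if both directions occur.
    """
    if control not in set(sample_meta["condition"]):
        raise ValueError(f"unknown control condition {control!r}")
    meta = sample_meta.loc[expr.values.columns]
    ctrl_samples = meta.index[meta["condition"] == control]
    ctrl_mean = expr.values[ctrl_samples].mean(axis=1)
    groups = (
        meta[meta["condition"] != control]
        .groupby(["condition", "timepoint"], sort=True)
        .groups
    )
    log2fc = {}
    for (cond, tp), samples in groups.items():
        mean_t = expr.values[list(samples)].mean(axis=1)
        log2fc[f"{tp}h"] = np.log2((mean_t + pseudo) / (ctrl_mean + pseudo))
    log2fc = pd.DataFrame(log2fc, index=expr.values.index)
    status = pd.DataFrame("none", index=log2fc.index, columns=log2fc.columns)
    status = status.mask(log2fc >= lfc_threshold, "up")
    status = status.mask(log2fc <= -lfc_threshold, "down")
    any_up = (status == "up").any(axis=1)
    any_down = (status == "down").any(axis=1)
    overall = pd.Series("none", index=log2fc.index, name="overall_status")
    overall[any_up] = "up"
    overall[any_down] = "down"
    overall[any_up & any_down] = "mixed"
    return DEResult(log2fc=log2fc, status=status, overall_status=overall)
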