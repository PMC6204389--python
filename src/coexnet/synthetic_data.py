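"""Synthetic inputs with planted structure for the co-expression pipeline.

Emulates a four-condition RNA-seq design (an inert control sugar at one time
point, an inducing substrate at three time points) for a fungal-scale gene
catalogue: negative-binomial-like counts with planted co-expression modules,
planted up/down differential expression, a small genome with promoters
carrying planted motif instances, and gene->term annotation tables with
planted enrichments.  Every generator exports its ground truth so that the
downstream stages (normalisation, network inference, module detection, motif
scanning, enrichment) can be tested for parameter recovery without any
external data.

Count model
-----------
Each module m has a latent per-sample profile on the log2 scale,

    P_m(s) = d_m * delta(s) + tau * Z_m(s),

where ``delta(s)`` is log2(de_fold) on substrate samples and 0 on control
samples, ``d_m`` is +1 / -1 / 0 for induced / repressed / non-responsive
modules, and ``Z_m`` is standard normal per sample (tau = 1.0 keeps modules
of the same direction distinguishable).  A gene in module m with loading
``rho_g`` has log2 profile

    y_g(s) = rho_g * P_m(s) + sqrt(1 - rho_g^2) * sd(P_m) * eps_g(s),

so the expected within-module correlation of two genes is rho_i * rho_j;
loadings are drawn in a narrow band around sqrt(within_module_cor), making
the mean pairwise correlation approximately the configured target.  Counts
are drawn per sample as a multinomial over gamma-perturbed rates
(the gamma-Poisson construction of the negative binomial conditioned on the
library size), so column sums land exactly inside ``library_size_range``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .expression_preprocess import CountMatrix

__all__ = [
    "SimConfig",
    "TruthBundle",
    "DEFAULT_CONDITIONS",
    "DEFAULT_MOTIF_CONSENSUS",
    "simulate_expression",
    "simulate_genome",
    "simulate_annotations",
    "write_genome_fasta",
    "write_gff3",
]

#: control sugar at 24 h plus the inducing substrate time course
DEFAULT_CONDITIONS: tuple[tuple[str, int], ...] = (
    ("fructose", 24),
    ("bagasse", 6),
    ("bagasse", 12),
    ("bagasse", 24),
)

#: 10-mer planted by default: an A-rich GGC(A/T)3-style core with a fixed tail,
#: wide enough that an exact match clears a 1e-4 scan threshold.
DEFAULT_MOTIF_CONSENSUS = "GGCAAATCGC"

_NUC = "ACGT"
_TAU = 1.2  # sd (log2) of the module-specific latent component
_BACKGROUND_SD = 0.3  # replicate-level log2 sd of genes outside modules
_LOADING_HALF_SPREAD = 0.05
_N_ANCHORS = 5  # designated anchor (hub-like) genes per module
_ANCHOR_LOADING = 1.0  # anchors carry the module's latent profile exactly


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-structure simulation.

    Defaults are the desk-scale study conditions used throughout the test
    suite: ~1,200 genes, six planted modules of 100 genes (two induced, two
    repressed, two condition-independent), 4 conditions x 3 replicates.
    """

    n_genes: int = 1200
    module_sizes: tuple[int, ...] = (100,) * 6
    conditions: tuple[tuple[str, int], ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    within_module_cor: float = 0.8
    de_fold: float = 4.0
    dispersion: float = 0.05
    gene_length_range: tuple[int, int] = (500, 5000)
    library_size_range: tuple[int, int] = (5_000_000, 15_000_000)
    promoter_length: int = 1500
    motif_plant_fraction: float = 0.5
    anticor_fraction: float = 0.0
    control_condition: str = "fructose"
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return len(self.conditions) * self.replicates_per_condition

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"sum of module sizes ({sum(self.module_sizes)}) exceeds "
                f"n_genes ({self.n_genes})"
            )
        if self.replicates_per_condition < 1:
            raise ConfigurationError("replicates_per_condition must be >= 1")
        if not (0.0 < self.within_module_cor <= 1.0):
            raise ConfigurationError("within_module_cor must be in (0, 1]")
        if self.de_fold <= 0:
            raise ConfigurationError("de_fold must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        for name in ("gene_length_range", "library_size_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must be a nonempty positive interval")
        if not (0.0 <= self.motif_plant_fraction <= 1.0):
            raise ConfigurationError("motif_plant_fraction must be in [0, 1]")
        if not (0.0 <= self.anticor_fraction <= 1.0):
            raise ConfigurationError("anticor_fraction must be in [0, 1]")
        if self.promoter_length <= 0:
            raise ConfigurationError("promoter_length must be positive")
        control = {c for c, _ in self.conditions}
        if self.control_condition not in control:
            raise ConfigurationError(
                f"control condition {self.control_condition!r} not among conditions"
            )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        data["conditions"] = [list(c) for c in self.conditions]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["conditions"] = tuple((c, int(t)) for c, t in data["conditions"])
        for name in ("module_sizes", "gene_length_range", "library_size_range"):
            if name in data:
                data[name] = tuple(data[name])
        return cls(**data)


@dataclass
class TruthBundle:
    """Ground truth exported by the generators for recovery tests."""

    module_of_gene: pd.Series  # gene -> module label, "background" otherwise
    module_direction: dict[str, str]  # module -> up/down/none
    de_status: pd.DataFrame  # genes x substrate timepoints, values up/down/none
    loadings: pd.Series  # gene -> correlation-scale loading (signed)
    eigenprofiles: pd.DataFrame  # modules x samples latent profiles
    planted_hits: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "offset", "strand"])
    )
    enriched_terms: dict[str, list[str]] = field(default_factory=dict)
    anchor_genes: list[str] = field(default_factory=list)

    def genes_in_module(self, module: str) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])

    def anchors(self, module: str) -> list[str]:
        """The designated highest-loading (hub-like) genes of a module."""
        return [g for g in self.anchor_genes
                if self.module_of_gene.get(g) == module]

    def write_tsvs(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.module_of_gene.rename("module").to_csv(
            directory / "truth_modules.tsv", sep="\t", index_label="gene"
        )
        self.de_status.to_csv(directory / "truth_de.tsv", sep="\t", index_label="gene")
        self.loadings.rename("loading").to_csv(
            directory / "truth_loadings.tsv", sep="\t", index_label="gene"
        )
        self.eigenprofiles.to_csv(
            directory / "truth_eigenprofiles.tsv", sep="\t", index_label="module"
        )
        self.planted_hits.to_csv(
            directory / "truth_planted_hits.tsv", sep="\t", index=False
        )
        rows = [
            {"module": m, "term": t}
            for m, terms in self.enriched_terms.items()
            for t in terms
        ]
        pd.DataFrame(rows, columns=["module", "term"]).to_csv(
            directory / "truth_enriched_terms.tsv", sep="\t", index=False
        )


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-component substreams from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _module_labels(n: int) -> list[str]:
    return [f"M{i + 1:02d}" for i in range(n)]


def _direction_pattern(n_modules: int) -> list[str]:
    # induced, repressed, non-responsive, repeating
    cycle = ["up", "down", "none"]
    return [cycle[i % 3] for i in range(n_modules)]


def _module_noise(
    rng: np.random.Generator,
    n_modules: int,
    n_samples: int,
    group_key: np.ndarray,
) -> np.ndarray:
    """Module-specific latent noise, orthogonal across modules.

    Each module's noise vector is centred within every (condition, timepoint)
    group, so the planted condition contrast is exact, and the vectors are
    orthogonalised against each other so that distinct planted modules are
    mutually distinguishable at the design's sample size (they differ only
    through these profiles plus the shared condition effect).  Each vector is
    scaled to per-sample standard deviation ~tau within the centred subspace.
    """
    groups = np.unique(group_key)
    free_dims = n_samples - len(groups)
    if n_modules == 0:
        return np.zeros((0, n_samples))
    if n_modules > free_dims:
        raise ConfigurationError(
            f"{n_modules} modules need more replicate degrees of freedom than "
            f"the design provides ({free_dims}); add replicates or conditions"
        )
    raw = rng.normal(size=(n_modules, n_samples))
    for key in groups:
        sel = group_key == key
        raw[:, sel] -= raw[:, sel].mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(raw.T)  # orthonormal basis of the centred noise
    q = q[:, :n_modules].T
    # deterministic sign: first nonzero component positive
    for i in range(n_modules):
        nz = np.flatnonzero(np.abs(q[i]) > 1e-12)
        if nz.size and q[i, nz[0]] < 0:
            q[i] = -q[i]
    return q * _TAU * math.sqrt(free_dims)


def simulate_expression(config: SimConfig) -> tuple[CountMatrix, TruthBundle]:
    """Simulate a count matrix with planted co-expression modules.

    Returns the raw counts (with gene lengths and sample metadata) and the
    :class:`TruthBundle` recording module membership, DE status, loadings and
    the latent module profiles.  Identical configs produce identical output.
    """
    rng_struct, rng_latent, rng_noise, rng_counts = _rngs(config.seed, 4)

    n_genes = config.n_genes
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    sample_rows = []
    for cond, tp in config.conditions:
        for r in range(1, config.replicates_per_condition + 1):
            sample_rows.append(
                {"sample": f"{cond}_{tp}h_r{r}", "condition": cond,
                 "timepoint": tp, "replicate": r}
            )
    sample_meta = pd.DataFrame(sample_rows).set_index("sample")
    samples = list(sample_meta.index)
    n_samples = len(samples)
    is_substrate = (sample_meta["condition"] != config.control_condition).to_numpy()

    labels = _module_labels(config.n_modules)
    directions = dict(zip(labels, _direction_pattern(config.n_modules)))
    module_of_gene = pd.Series("background", index=gene_ids, name="module")
    pos = 0
    for lab, size in zip(labels, config.module_sizes):
        module_of_gene.iloc[pos:pos + size] = lab
        pos += size

    # latent module profiles (log2 scale); the module-specific noise is
    # centred within each (condition, timepoint) group so the planted
    # condition contrast is exactly log2(de_fold) at the latent level
    log2_fold = math.log2(config.de_fold)
    delta = np.where(is_substrate, log2_fold, 0.0)
    group_key = (sample_meta["condition"].astype(str) + "@"
                 + sample_meta["timepoint"].astype(str)).to_numpy()
    noise = _module_noise(
        rng_latent, config.n_modules, n_samples, group_key
    )
    eigenprofiles = {}
    for mi, lab in enumerate(labels):
        d = {"up": 1.0, "down": -1.0, "none": 0.0}[directions[lab]]
        eigenprofiles[lab] = d * delta + noise[mi]
    eigenprofiles = pd.DataFrame(eigenprofiles, index=samples).T
    eigenprofiles.index.name = "module"

    # loadings: a narrow band around sqrt(target correlation), plus a few
    # designated near-unit-loading anchor genes per module (hub structure)
    sqrt_r = math.sqrt(config.within_module_cor)
    half = min(_LOADING_HALF_SPREAD, 1.0 - sqrt_r)
    loadings = pd.Series(0.0, index=gene_ids, name="loading")
    in_module = module_of_gene != "background"
    n_mod_genes = int(in_module.sum())
    rho = sqrt_r + rng_struct.uniform(-half, half, size=n_mod_genes)
    if config.anticor_fraction > 0:
        flip = rng_struct.random(n_mod_genes) < config.anticor_fraction
        rho = np.where(flip, -rho, rho)
    loadings[in_module] = rho
    anchor_loading = max(_ANCHOR_LOADING, min(1.0, sqrt_r + half))
    anchor_genes: list[str] = []
    for lab, size in zip(labels, config.module_sizes):
        genes = module_of_gene.index[module_of_gene == lab]
        chosen = rng_struct.choice(len(genes), size=min(_N_ANCHORS, size),
                                   replace=False)
        for gi in chosen:
            g = genes[gi]
            loadings[g] = math.copysign(anchor_loading, loadings[g])
            anchor_genes.append(g)

    # per-gene log2 profiles
    y = np.zeros((n_genes, n_samples))
    baseline = rng_struct.normal(3.5, 1.5, size=n_genes)
    for i, g in enumerate(gene_ids):
        lab = module_of_gene.iloc[i]
        if lab == "background":
            y[i] = rng_noise.normal(0.0, _BACKGROUND_SD, size=n_samples)
        else:
            p = eigenprofiles.loc[lab].to_numpy()
            sd_p = float(p.std())
            r_g = loadings.iloc[i]
            y[i] = r_g * p + math.sqrt(max(0.0, 1.0 - r_g**2)) * sd_p * (
                rng_noise.normal(size=n_samples)
            )

    lengths = rng_struct.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n_genes
    )
    rates = (lengths[:, None] / 1000.0) * np.exp2(baseline[:, None] + y)

    # gamma-Poisson overdispersion, then multinomial conditioning on the
    # library size so that column sums land inside library_size_range exactly
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        rates = rates * rng_counts.gamma(shape, config.dispersion, size=rates.shape)
    lib_lo, lib_hi = config.library_size_range
    lib_sizes = rng_counts.integers(lib_lo, lib_hi + 1, size=n_samples)
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = rates[:, j] / rates[:, j].sum()
        counts[:, j] = rng_counts.multinomial(lib_sizes[j], p)

    count_matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
        sample_meta=sample_meta,
    )

    substrate_tps = sorted(
        {tp for cond, tp in config.conditions if cond != config.control_condition}
    )
    de_status = pd.DataFrame("none", index=gene_ids, columns=[f"{t}h" for t in substrate_tps])
    for lab in labels:
        direction = directions[lab]
        if direction == "none":
            continue
        genes = module_of_gene.index[module_of_gene == lab]
        de_status.loc[genes, :] = direction

    truth = TruthBundle(
        module_of_gene=module_of_gene,
        module_direction=directions,
        de_status=de_status,
        loadings=loadings,
        eigenprofiles=eigenprofiles,
        anchor_genes=anchor_genes,
    )
    return count_matrix, truth


# ---------------------------------------------------------------------------
# genome + promoters with planted motif instances
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(
    genes: Sequence[str],
    config: SimConfig,
    consensus: str = DEFAULT_MOTIF_CONSENSUS,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    genes_per_contig: int = 50,
    cds_length: int = 300,
    planted_genes: Sequence[str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Emit contigs carrying the genes on alternating strands.

    Promoters (``config.promoter_length`` bp immediately upstream of the ATG
    on the gene's sense strand) are drawn from a 0-order background; for
    planted genes one exact-consensus instance is written at a uniformly drawn
    offset, on a uniformly drawn strand relative to the gene.  Returns
    ``(contigs, gene_models, planted_hits)`` where offsets follow the hit
    convention (5'-most base on the sense orientation, -1 adjacent to ATG).
    """
    width = len(consensus)
    if config.promoter_length < width:
        raise ConfigurationError(
            f"promoter_length ({config.promoter_length}) shorter than motif "
            f"width ({width})"
        )
    if any(b not in _NUC for b in consensus):
        raise ConfigurationError("consensus must be over ACGT")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ConfigurationError("background must be 4 probabilities summing to 1")

    rng_seq, rng_plant = _rngs(config.seed + 1, 2)
    if planted_genes is None:
        n_plant = int(round(config.motif_plant_fraction * len(genes)))
        planted = set(rng_plant.choice(len(genes), size=n_plant, replace=False))
        planted_genes = {genes[i] for i in planted}
    else:
        planted_genes = set(planted_genes)

    prom, spacer = config.promoter_length, 100
    contigs: dict[str, list[str]] = {}
    models = []
    hits = []
    for ci in range(0, len(genes), genes_per_contig):
        name = f"contig{ci // genes_per_contig + 1:03d}"
        chunk = genes[ci:ci + genes_per_contig]
        length = len(chunk) * (prom + cds_length + spacer)
        seq = rng_seq.choice(list(_NUC), p=bg, size=length)
        cursor = 0  # 0-based
        for k, gene in enumerate(chunk):
            strand = "+" if k % 2 == 0 else "-"
            if strand == "+":
                atg0 = cursor + prom  # 0-based position of the A of ATG
                cds_start, cds_end = atg0 + 1, atg0 + cds_length
                seq[atg0:atg0 + 3] = list("ATG")
            else:
                cds_start = cursor + 1
                cds_end = cursor + cds_length
                atg0 = cds_end - 1  # 0-based position of genomic base at cds_end
                seq[atg0 - 2:atg0 + 1] = list("CAT")  # sense ATG on minus strand
            if gene in planted_genes:
                offset = int(rng_plant.integers(-prom, -width + 1))
                motif_strand = "+" if rng_plant.random() < 0.5 else "-"
                word = consensus if motif_strand == "+" else _revcomp(consensus)
                if strand == "+":
                    start0 = atg0 + offset  # sense coords run left to right
                    seq[start0:start0 + width] = list(word)
                else:
                    # sense position p maps to genomic (0-based) atg0 - p - ...
                    # promoter sense window [offset, offset+width-1] is the
                    # reverse complement of genomic [atg0+1-offset-width+1 ...]
                    end0 = atg0 + 1 - offset - 1  # genomic 0-based of sense 'offset'
                    start0 = end0 - width + 1
                    seq[start0:start0 + width] = list(_revcomp(word))
                hits.append({"gene": gene, "offset": offset, "strand": motif_strand})
            models.append(
                {"gene": gene, "contig": name, "strand": strand,
                 "cds_start": cds_start, "cds_end": cds_end}
            )
            cursor += prom + cds_length + spacer
        contigs[name] = "".join(seq)
    gene_models = pd.DataFrame(
        models, columns=["gene", "contig", "strand", "cds_start", "cds_end"]
    )
    planted_hits = pd.DataFrame(hits, columns=["gene", "offset", "strand"])
    return contigs, gene_models, planted_hits


def write_genome_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(gene_models: pd.DataFrame, path: str | Path) -> None:
    """Write gene/mRNA/CDS features (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for _, row in gene_models.iterrows():
        g, c, st = row["gene"], row["contig"], row["strand"]
        s, e = int(row["cds_start"]), int(row["cds_end"])
        lines.append(f"{c}\tcoexnet\tgene\t{s}\t{e}\t.\t{st}\t.\tID={g}")
        lines.append(f"{c}\tcoexnet\tmRNA\t{s}\t{e}\t.\t{st}\t.\tID={g}.t1;Parent={g}")
        lines.append(f"{c}\tcoexnet\tCDS\t{s}\t{e}\t.\t{st}\t0\tID={g}.cds;Parent={g}.t1")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# annotation tables with planted enrichments
# ---------------------------------------------------------------------------

def simulate_annotations(
    truth: TruthBundle,
    n_terms: int,
    enrichment_fold: float = 8.0,
    seed: int = 0,
    background_freq_range: tuple[float, float] = (0.02, 0.08),
    namespace: str = "GO",
) -> pd.DataFrame:
    """Assign terms to genes, enriching one planted term per module.

    Every term has a background assignment probability drawn from
    ``background_freq_range``; the planted term of each module is assigned to
    that module's genes with probability ``min(1, enrichment_fold * p_bg)``
    while all other gene-term assignments are independent of module labels.
    Updates ``truth.enriched_terms`` and returns a (gene, term, namespace)
    table.
    """
    if enrichment_fold < 1:
        raise ConfigurationError("enrichment_fold must be >= 1")
    if n_terms < 0:
        raise ConfigurationError("n_terms must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(truth.module_of_gene.index)
    modules = [m for m in truth.module_of_gene.unique() if m != "background"]
    if n_terms == 0:
        truth.enriched_terms = {}
        return pd.DataFrame(columns=["gene", "term", "namespace"])

    terms = [f"{namespace}:{i + 1:07d}" for i in range(n_terms)]
    p_bg = rng.uniform(*background_freq_range, size=n_terms)
    planted: dict[str, list[str]] = {}
    term_of_module = {}
    for i, m in enumerate(modules):
        if i < n_terms:
            term_of_module[m] = i
            planted[m] = [terms[i]]
    rows = []
    module_arr = truth.module_of_gene.to_numpy()
    for t_idx, term in enumerate(terms):
        p = np.full(len(genes), p_bg[t_idx])
        for m, idx in term_of_module.items():
            if idx == t_idx:
                p = np.where(module_arr == m, min(1.0, enrichment_fold * p_bg[t_idx]), p)
        keep = rng.random(len(genes)) < p
        rows.extend(
            {"gene": g, "term": term, "namespace": namespace}
            for g, k in zip(genes, keep) if k
        )
    truth.enriched_terms = planted
    return pd.DataFrame(rows, columns=["gene", "term", "namespace"])
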