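"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three data modalities:

* Hi-C: symmetric distance-decaying contact matrices with planted enriched
  gene-body blocks, expectation ``base_intensity * (1 + |i-j|)**(-alpha)``
  times the enrichment factor inside planted blocks, with optional Poisson
  noise.  Ground-truth GAD labels come back with the matrix.
* Expression: two sample series (a developmental and an activation series)
  in which one driver transcription factor trends monotonically (up in
  development, down upon activation) and the target gene tracks it
  linearly; decoy TFs vary independently.
* Single-cell: negative-binomial counts for two populations in which an
  exhausted population overexpresses a marker set by a fold factor, with
  controlled per-cell mitochondrial fractions and, on request, cells built
  to fail specific QC criteria.

All generators are bit-reproducible for a fixed seed, and every returned
truth label is sufficient to score downstream recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_score import EXHAUSTION_MARKERS, CellCounts
from .contact import ContactMatrix
from .gad import GeneModel

__all__ = [
    "HicSimParams",
    "ExprSimParams",
    "ScSimParams",
    "ScreenInputs",
    "planted_grid",
    "simulate_contact_matrix",
    "simulate_expression_series",
    "simulate_cell_counts",
    "simulate_deg_table",
    "simulate_screen_inputs",
]


def planted_grid(
    n_bins: int,
    n_planted: int,
    enrichment: float,
    bin_size: int = 10_000,
    gene_bins: int = 4,
    edge: int = 8,
) -> tuple:
    """Evenly spaced planted-gene intervals for :class:`HicSimParams`.

    Places ``n_planted`` genes of ``gene_bins`` bins between ``edge`` and
    ``n_bins - edge``, leaving room for flanks and inter-gene margins;
    raises if the matrix is too small for that layout.
    """
    if n_planted == 0:
        return ()
    starts = (
        np.linspace(edge, n_bins - edge - gene_bins, n_planted)
        .round()
        .astype(int)
    )
    if n_planted > 1 and int(np.diff(starts).min()) < gene_bins + 2:
        raise ValueError(
            f"{n_bins} bins cannot hold {n_planted} planted {gene_bins}-bin genes"
        )
    return tuple(
        (
            (int(s) * bin_size, (int(s) + gene_bins) * bin_size),
            float(enrichment),
        )
        for s in starts
    )


# ---------------------------------------------------------------------------
# Hi-C


@dataclass(frozen=True)
class HicSimParams:
    """Parameters of the contact-matrix generator.

    ``planted_genes`` is a list of ``((start, end), enrichment)`` pairs in
    base coordinates; the square block of bins each interval overlaps is
    multiplied by its enrichment factor.  Decoy genes (40 kb, unenriched)
    and one sub-30 kb gene are placed automatically in the remaining space.
    """

    n_bins: int = 200
    bin_size: int = 10_000
    decay_exponent: float = 1.0
    base_intensity: float = 100.0
    planted_genes: tuple = ()
    noise: str = "poisson"
    seed: int = 0
    chrom: str = "chrS"
    max_decoys: int | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 10:
            raise ValueError(f"n_bins must be >= 10, got {self.n_bins}")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.noise not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        extent = self.n_bins * self.bin_size
        for (start, end), e in self.planted_genes:
            if e < 1:
                raise ValueError(f"enrichment factor must be >= 1, got {e}")
            if not (0 <= start < end <= extent):
                raise ValueError(
                    f"planted gene [{start}, {end}) outside chromosome "
                    f"extent [0, {extent})"
                )


def _interval_bins(start: int, end: int, bin_size: int) -> tuple[int, int]:
    return start // bin_size, -(-end // bin_size)


def simulate_contact_matrix(
    params: HicSimParams,
) -> tuple[ContactMatrix, list[GeneModel], pd.DataFrame]:
    """Generate a contact matrix with planted GADs and a gene annotation.

    Returns ``(matrix, genes, labels)`` where ``labels`` has one row per
    gene with its ``is_gad`` ground truth.  The gene list contains the
    planted genes, automatically placed 40 kb decoy genes with full flank
    room, and one 20 kb gene (ineligible for GAD scoring by construction).
    """
    p = params
    idx = np.arange(p.n_bins)
    dist = np.abs(np.subtract.outer(idx, idx))
    expected = p.base_intensity * (1.0 + dist) ** (-p.decay_exponent)

    # enrichment multiplies the off-diagonal entries of the gene-body block
    # only: the main diagonal is self-ligation signal, which domain
    # formation does not amplify (and which the GAD statistic never reads)
    planted_ranges = []
    for (start, end), e in p.planted_genes:
        lo, hi = _interval_bins(start, end, p.bin_size)
        block_diag = np.diag(expected[lo:hi, lo:hi]).copy()
        expected[lo:hi, lo:hi] *= e
        expected[lo:hi, lo:hi][np.diag_indices(hi - lo)] = block_diag
        planted_ranges.append((lo, hi))

    if p.noise == "poisson":
        rng = np.random.default_rng(p.seed)
        iu = np.triu_indices(p.n_bins)
        values = np.zeros_like(expected)
        values[iu] = rng.poisson(expected[iu]).astype(float)
        values = values + values.T - np.diag(np.diag(values))
    else:
        values = expected

    matrix = ContactMatrix(chrom=p.chrom, bin_size=p.bin_size, values=values)

    genes: list[GeneModel] = []
    labels = []
    for k, ((start, end), e) in enumerate(p.planted_genes):
        gid = f"GAD{k + 1:03d}"
        genes.append(GeneModel(gid, p.chrom, int(start), int(end)))
        labels.append({"gene_id": gid, "is_gad": True, "enrichment": float(e)})

    # decoys: 4-bin (40 kb) unenriched genes with a 1-bin margin from
    # planted blocks and enough edge margin for their flanks
    gene_bins = 4
    occupied = np.zeros(p.n_bins, dtype=bool)
    for lo, hi in planted_ranges:
        occupied[max(0, lo - 1) : min(p.n_bins, hi + 1)] = True
    edge = gene_bins + 2
    max_decoys = p.max_decoys if p.max_decoys is not None else p.n_bins

    short_placed = False
    pos = edge
    n_placed = 0
    while pos + gene_bins <= p.n_bins - edge:
        if not short_placed and not occupied[pos : pos + 2].any():
            gid = "SHORT001"
            genes.append(
                GeneModel(gid, p.chrom, pos * p.bin_size, pos * p.bin_size + 20_000)
            )
            labels.append({"gene_id": gid, "is_gad": False, "enrichment": 1.0})
            occupied[pos : pos + 2] = True
            short_placed = True
            pos += 3
            continue
        if n_placed >= max_decoys:
            break
        if not occupied[pos : pos + gene_bins].any():
            n_placed += 1
            gid = f"GEN{n_placed:03d}"
            genes.append(
                GeneModel(
                    gid,
                    p.chrom,
                    pos * p.bin_size,
                    (pos + gene_bins) * p.bin_size,
                )
            )
            labels.append({"gene_id": gid, "is_gad": False, "enrichment": 1.0})
            occupied[pos : pos + gene_bins] = True
            pos += gene_bins + 1
        else:
            pos += 1

    return matrix, genes, pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# Expression series


@dataclass(frozen=True)
class ExprSimParams:
    """Parameters of the two-series expression generator.

    ``driver_effect`` is the slope linking the driver TF to the target;
    ``trend`` is the amplitude of the monotone stage trend (the driver and
    target rise by ``trend`` across the development series and fall by it
    across the activation series).  Decoy TFs have unit-variance intrinsic
    variation independent of the target.
    """

    n_samples: int = 20
    n_tfs: int = 50
    driver_effect: float = 1.0
    noise_sd: float = 0.5
    trend: float = 2.0
    target_gene: str = "INPP4B"
    baseline: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError(f"n_samples must be >= 4, got {self.n_samples}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_tfs < 1:
            raise ValueError("need at least one TF")


def simulate_expression_series(
    params: ExprSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, str, list[str]]:
    """Generate development and activation expression tables.

    Returns ``(dev, act, driver_id, decoy_ids)``; rows are genes (target +
    TFs), columns are samples in stage/time order.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    t = np.linspace(0.0, 1.0, p.n_samples)
    tf_ids = [f"TF{i + 1:03d}" for i in range(p.n_tfs)]
    driver = tf_ids[0]
    decoys = tf_ids[1:]

    def one_series(trend_dir: float) -> pd.DataFrame:
        drv = (
            p.baseline
            + p.trend * (t if trend_dir > 0 else 1.0 - t)
            + rng.normal(0.0, p.noise_sd, p.n_samples)
        )
        target = (
            p.driver_effect * drv
            + p.trend * (t if trend_dir > 0 else 1.0 - t)
            + rng.normal(0.0, p.noise_sd, p.n_samples)
        )
        rows = {p.target_gene: target, driver: drv}
        for tf in decoys:
            rows[tf] = p.baseline + rng.normal(0.0, 1.0, p.n_samples)
        return pd.DataFrame(rows).T

    dev = one_series(+1.0)
    dev.columns = [f"dev_s{i + 1:02d}" for i in range(p.n_samples)]
    act = one_series(-1.0)
    act.columns = [f"act_s{i + 1:02d}" for i in range(p.n_samples)]
    dev.index.name = act.index.name = "gene_id"
    return dev, act, driver, decoys


# ---------------------------------------------------------------------------
# DE summary tables and the full screen input bundle


def simulate_deg_table(
    n_genes: int,
    n_up: int,
    n_down: int,
    seed: int,
    gene_ids: list[str] | None = None,
    up_ids: list[str] | None = None,
    down_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Differential-expression summary with planted directional hits.

    Planted up genes get log2FC > 1 with p < .05; planted down genes
    log2FC < -1 with p < .05; every other row fails at least one of the
    two criteria.  By default the first ``n_up`` genes are up and the next
    ``n_down`` down; explicit id lists override that.
    """
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    if n_up + n_down > n_genes:
        raise ValueError("n_up + n_down must not exceed n_genes")
    up = list(up_ids) if up_ids is not None else gene_ids[:n_up]
    down = list(down_ids) if down_ids is not None else gene_ids[n_up : n_up + n_down]
    if len(up) != n_up or len(down) != n_down:
        raise ValueError("planted id lists must match n_up / n_down")
    if set(up) & set(down):
        raise ValueError("a gene cannot be planted both up and down")

    rng = np.random.default_rng(seed)
    rows = []
    up_set, down_set = set(up), set(down)
    for gid in gene_ids:
        if gid in up_set:
            lfc = rng.uniform(1.5, 3.0)
            p = 10.0 ** rng.uniform(-4.0, -2.0)
            planted = "up"
        elif gid in down_set:
            lfc = -rng.uniform(1.5, 3.0)
            p = 10.0 ** rng.uniform(-4.0, -2.0)
            planted = "down"
        else:
            lfc = rng.uniform(-2.5, 2.5)
            p = rng.uniform(0.06, 1.0) if abs(lfc) > 1.0 else rng.uniform(0.0, 1.0)
            planted = ""
        rows.append(
            {"gene_id": gid, "log2FC": round(lfc, 6), "p": p, "planted": planted}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScreenInputs:
    """Bundle of all four TF-screen inputs plus ground truth."""

    dev_expr: pd.DataFrame
    act_expr: pd.DataFrame
    dev_deg: pd.DataFrame
    act_deg: pd.DataFrame
    driver: str
    tf_ids: list[str]
    target_gene: str


def simulate_screen_inputs(
    params: ExprSimParams, n_confounders: int = 5
) -> ScreenInputs:
    """Expression series plus matched DE tables with one true driver.

    The driver is planted up in the development table and down in the
    activation table.  ``n_confounders`` decoy TFs get the same
    directional pattern (so they pass the direction filter and must be
    rejected by the correlation screen); truth is the single driver.
    """
    dev, act, driver, decoys = simulate_expression_series(params)
    if n_confounders > len(decoys):
        raise ValueError("more confounders than decoy TFs")
    confounders = decoys[:n_confounders]
    gene_ids = list(dev.index)
    up = [driver, *confounders]
    dev_deg = simulate_deg_table(
        len(gene_ids), len(up), 0, params.seed + 1, gene_ids=gene_ids, up_ids=up
    )
    act_deg = simulate_deg_table(
        len(gene_ids), 0, len(up), params.seed + 2, gene_ids=gene_ids, down_ids=up
    )
    return ScreenInputs(
        dev_expr=dev,
        act_expr=act,
        dev_deg=dev_deg,
        act_deg=act_deg,
        driver=driver,
        tf_ids=[driver, *decoys],
        target_gene=params.target_gene,
    )


# ---------------------------------------------------------------------------
# Single-cell counts


@dataclass(frozen=True)
class ScSimParams:
    """Parameters of the two-population single-cell count generator.

    ``marker_fold`` multiplies the marker genes' negative-binomial means in
    the exhausted population; ``co_upregulated`` genes get the same fold
    but are not part of the scored marker set (useful as query genes).
    ``n_low_gene_cells`` / ``n_low_umi_cells`` / ``n_high_mito_cells``
    append cells constructed to fail exactly one QC criterion each.
    """

    n_cells: int = 200
    n_genes: int = 2000
    nb_mean: float = 1.0
    nb_dispersion: float = 2.0
    marker_genes: tuple[str, ...] = EXHAUSTION_MARKERS
    marker_fold: float = 4.0
    mito_fraction_range: tuple[float, float] = (0.01, 0.08)
    co_upregulated: tuple[str, ...] = ()
    n_mito_genes: int = 10
    n_low_gene_cells: int = 0
    n_low_umi_cells: int = 0
    n_high_mito_cells: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("mito_fraction_range must lie within [0, 1)")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("negative-binomial parameters must be positive")
        n_named = (
            len(self.marker_genes) + len(self.co_upregulated) + self.n_mito_genes
        )
        if n_named >= self.n_genes:
            raise ValueError("n_genes too small for the named genes")


def simulate_cell_counts(params: ScSimParams) -> tuple[CellCounts, pd.Series]:
    """Generate raw counts for a naive and an exhausted population.

    Returns ``(counts, labels)`` with per-cell labels ``"naive"``,
    ``"exhausted"`` or ``"qc_fail"`` (for the optional planted QC
    failures).  Marker (and co-upregulated) genes have their NB means
    multiplied by ``marker_fold`` in the exhausted population; each cell's
    mitochondrial counts realise a fraction drawn uniformly from
    ``mito_fraction_range``.
    """
    p = params
    for g in p.co_upregulated:
        if g in p.marker_genes:
            raise ValueError(f"{g} cannot be both a marker and co-upregulated")
    rng = np.random.default_rng(p.seed)

    mito_ids = [f"MT-{i + 1}" for i in range(p.n_mito_genes)]
    named = [*p.marker_genes, *p.co_upregulated, *mito_ids]
    filler = [f"G{i + 1:04d}" for i in range(p.n_genes - len(named))]
    genes = [*named, *filler]
    missing = [g for g in p.marker_genes if g not in genes]
    if missing:  # unreachable with the default naming; guards custom lists
        raise ValueError(f"marker genes not among simulated genes: {missing}")

    non_mito = [g for g in genes if g not in mito_ids]
    gene_means = pd.Series(
        rng.lognormal(mean=np.log(p.nb_mean), sigma=1.0, size=len(non_mito)),
        index=non_mito,
    )

    def draw_population(n: int, fold_genes: set[str]) -> np.ndarray:
        mu = gene_means.copy()
        mu[mu.index.isin(fold_genes)] *= p.marker_fold
        r = p.nb_dispersion
        prob = r / (r + mu.to_numpy())
        return rng.negative_binomial(
            r, prob[:, None], size=(len(non_mito), n)
        ).astype(np.int64)

    up_genes = set(p.marker_genes) | set(p.co_upregulated)
    naive = draw_population(p.n_cells, set())
    exhausted = draw_population(p.n_cells, up_genes)
    body = np.concatenate([naive, exhausted], axis=1)
    labels = ["naive"] * p.n_cells + ["exhausted"] * p.n_cells
    cells = [f"NAI_{i + 1:04d}" for i in range(p.n_cells)] + [
        f"EXH_{i + 1:04d}" for i in range(p.n_cells)
    ]

    # mitochondrial counts realising the drawn per-cell fraction
    fracs = rng.uniform(*p.mito_fraction_range, size=body.shape[1])
    non_mito_tot = body.sum(axis=0)
    mito_tot = np.round(fracs / (1.0 - fracs) * non_mito_tot).astype(np.int64)
    mito_block = np.zeros((p.n_mito_genes, body.shape[1]), dtype=np.int64)
    probs = np.full(p.n_mito_genes, 1.0 / p.n_mito_genes)
    for j, tot in enumerate(mito_tot):
        mito_block[:, j] = rng.multinomial(tot, probs)

    # optional planted QC failures (each violating exactly one criterion)
    extra_cols, extra_cells = [], []
    for i in range(p.n_low_gene_cells):
        col = np.zeros(p.n_genes, dtype=np.int64)
        col[len(mito_ids) : len(mito_ids) + 399] = 3  # 399 genes, 1197 UMIs
        extra_cols.append(col)
        extra_cells.append(f"LQG_{i + 1:03d}")
    for i in range(p.n_low_umi_cells):
        col = np.zeros(p.n_genes, dtype=np.int64)
        col[len(mito_ids) : len(mito_ids) + 450] = 1
        col[len(mito_ids)] += 549  # 450 genes, 999 UMIs
        extra_cols.append(col)
        extra_cells.append(f"LQU_{i + 1:03d}")
    for i in range(p.n_high_mito_cells):
        col = np.zeros(p.n_genes, dtype=np.int64)
        col[len(mito_ids) : len(mito_ids) + 500] = 2
        col[:p.n_mito_genes] = 250 // p.n_mito_genes  # 20% mito
        extra_cols.append(col)
        extra_cells.append(f"LQM_{i + 1:03d}")

    # assemble in gene order: markers/co-up/mito/filler
    full = np.zeros((p.n_genes, body.shape[1]), dtype=np.int64)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for row, g in enumerate(non_mito):
        full[gene_pos[g], :] = body[row, :]
    for row, g in enumerate(mito_ids):
        full[gene_pos[g], :] = mito_block[row, :]

    if extra_cols:
        # planted failures index genes in non-mito-first layout; rebuild
        extras = np.zeros((p.n_genes, len(extra_cols)), dtype=np.int64)
        nm_first = [*mito_ids, *non_mito]
        for j, col in enumerate(extra_cols):
            for row_src, g in enumerate(nm_first):
                extras[gene_pos[g], j] = col[row_src]
        full = np.concatenate([full, extras], axis=1)
        cells = cells + extra_cells
        labels = labels + ["qc_fail"] * len(extra_cells)

    counts = CellCounts(
        genes=genes, cells=cells, counts=full, mito_genes=frozenset(mito_ids)
    )
    return counts, pd.Series(labels, index=pd.Index(cells, name="cell"), name="label")
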