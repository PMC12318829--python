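"""Gene-body-associated-domain (GAD) scoring and significance calling.

A GAD is a chromatin interaction domain coinciding with a gene body.  For
each gene longer than 30 kb spanning at least 3 bins, the mean contact
intensity within the gene-body block (G) is compared with equal-length
upstream (Gu) and downstream (Gd) flank blocks:

    Gs = 2 * G / (Gu + Gd)

Genes on a uniform matrix score exactly 1; genes whose bodies form an
enriched self-interacting block score above 1.  Significant GADs (sig-GADs)
are genes with Gs > 1 whose rank on the ascending score curve lies past the
point where the min-max-rescaled curve's slope passes 1 (the tangent-point
rule used for super-enhancer rank curves).

Block means are taken over the off-diagonal upper triangle of each square
block by default: the main diagonal is dominated by self-ligation signal
and would compress Gs toward 1.  Flanks are measured in bins (one gene
length each side); genes whose flanks leave the matrix are undefined
("edge") rather than truncated.  "Upstream" means lower genomic
coordinates; strand is ignored for geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from math import isfinite

import numpy as np
import pandas as pd

from .contact import ContactMatrix
from .stats import ranksum

__all__ = [
    "GeneModel",
    "GadRecord",
    "SigGadParams",
    "map_gene_to_bins",
    "compute_gad_score",
    "score_all_genes",
    "call_sig_gads",
    "compare_gad_scores",
    "read_genes_bed",
    "write_genes_bed",
    "records_to_frame",
]

logger = logging.getLogger(__name__)

#: minimum gene length in bases for GAD eligibility
MIN_GENE_LENGTH = 30_000
#: minimum gene-body bin count for GAD eligibility
MIN_GENE_BINS = 3


@dataclass(frozen=True)
class GeneModel:
    """Gene interval, 0-based half-open, on one chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"{self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GadRecord:
    """Per-gene GAD statistics.

    ``g``, ``gu``, ``gd`` are the mean block intensities of the gene body
    and its upstream/downstream flanks; ``gs = 2*g/(gu+gd)``.  All four are
    NaN when the score is undefined (``undefined_reason`` says why).  The
    ``sig`` flag is set by :func:`call_sig_gads`.
    """

    gene_id: str
    g: float
    gu: float
    gd: float
    gs: float
    n_bins: int
    eligible: bool
    undefined_reason: str | None = None
    sig: bool = False

    @property
    def defined(self) -> bool:
        return self.eligible and isfinite(self.gs)


@dataclass(frozen=True)
class SigGadParams:
    """Parameters of the sig-GAD caller."""

    score_floor: float = 1.0
    knee_method: str = "rescaled_slope1"
    min_genes: int = 10

    def __post_init__(self) -> None:
        if self.score_floor <= 0:
            raise ValueError("score_floor must be positive")
        if self.knee_method != "rescaled_slope1":
            raise ValueError(f"unknown knee method {self.knee_method!r}")


def map_gene_to_bins(g: GeneModel, m: ContactMatrix) -> tuple[int, int]:
    """Half-open bin range covering all bins that overlap the gene by >= 1 bp.

    Raises ``ValueError`` on chromosome mismatch or a gene wholly outside
    the matrix extent.
    """
    if g.chrom != m.chrom:
        raise ValueError(
            f"{g.gene_id}: gene chromosome {g.chrom!r} does not match "
            f"matrix chromosome {m.chrom!r}"
        )
    if g.start >= m.extent or g.end <= 0:
        raise ValueError(f"{g.gene_id}: gene outside matrix extent")
    lo = max(g.start, 0) // m.bin_size
    hi = -(-min(g.end, m.extent) // m.bin_size)  # ceil division
    return int(lo), int(hi)


def _block_mean(values: np.ndarray, a: int, b: int, include_diagonal: bool) -> float:
    """Mean over the upper triangle of the square block ``[a:b, a:b]``."""
    block = values[a:b, a:b]
    k = 0 if include_diagonal else 1
    iu = np.triu_indices(b - a, k=k)
    return float(block[iu].mean())


def compute_gad_score(
    g: GeneModel,
    m: ContactMatrix,
    include_diagonal: bool = False,
    flank_mode: str = "square",
) -> GadRecord:
    """Score one gene against a (balanced) contact matrix.

    Eligibility requires gene length > 30 kb AND >= 3 gene-body bins.  With
    ``flank_mode="square"`` (default) Gu and Gd are the within-flank block
    means; ``"rectangle"`` instead averages the gene-vs-flank rectangular
    blocks.  Undefined scores carry a reason: ``"too_short"`` (ineligible),
    ``"edge"`` (flank leaves the matrix), ``"zero_flanks"`` (Gu + Gd = 0).
    """
    if flank_mode not in ("square", "rectangle"):
        raise ValueError(f"unknown flank_mode {flank_mode!r}")
    nan = float("nan")
    try:
        lo, hi = map_gene_to_bins(g, m)
    except ValueError:
        if g.chrom != m.chrom:
            raise
        return GadRecord(g.gene_id, nan, nan, nan, nan, 0, False, "edge")
    n = hi - lo
    if g.length <= MIN_GENE_LENGTH or n < MIN_GENE_BINS:
        return GadRecord(g.gene_id, nan, nan, nan, nan, n, False, "too_short")
    if lo - n < 0 or hi + n > m.n_bins:
        return GadRecord(g.gene_id, nan, nan, nan, nan, n, True, "edge")

    body = _block_mean(m.values, lo, hi, include_diagonal)
    if flank_mode == "square":
        gu = _block_mean(m.values, lo - n, lo, include_diagonal)
        gd = _block_mean(m.values, hi, hi + n, include_diagonal)
    else:
        gu = float(m.values[lo:hi, lo - n : lo].mean())
        gd = float(m.values[lo:hi, hi : hi + n].mean())
    if gu + gd == 0.0:
        return GadRecord(g.gene_id, body, gu, gd, nan, n, True, "zero_flanks")
    return GadRecord(
        g.gene_id, body, gu, gd, 2.0 * body / (gu + gd), n, True, None
    )


def score_all_genes(
    genes: list[GeneModel],
    m: ContactMatrix,
    include_diagonal: bool = False,
    flank_mode: str = "square",
) -> list[GadRecord]:
    """Score every gene; per-gene failures become undefined records.

    A gene annotated on a different chromosome than the matrix is recorded
    as undefined ("edge") instead of raising, so one bad annotation cannot
    abort a whole run.
    """
    records: list[GadRecord] = []
    for g in genes:
        if g.chrom != m.chrom:
            nan = float("nan")
            records.append(GadRecord(g.gene_id, nan, nan, nan, nan, 0, False, "edge"))
            continue
        records.append(compute_gad_score(g, m, include_diagonal, flank_mode))
    reasons = pd.Series(
        [r.undefined_reason or "defined" for r in records]
    ).value_counts()
    logger.info("scored %d genes: %s", len(records), reasons.to_dict())
    return records


def call_sig_gads(
    records: list[GadRecord], params: SigGadParams | None = None
) -> tuple[list[GadRecord], float | None]:
    """Flag significant GADs; returns (records with sig set, cutoff score).

    Defined scores are sorted ascending (ties broken by gene id), both rank
    and score are min-max rescaled to [0, 1], and the cutoff rank is the
    argmin of (rescaled score - rescaled rank) — the tangent point where
    the curve's slope passes 1.  A gene is significant iff its rank exceeds
    the cutoff rank and its Gs exceeds ``score_floor``.  With fewer than
    ``min_genes`` defined scores only the floor rule applies; with a flat
    score curve nothing is significant.
    """
    params = params or SigGadParams()
    defined = sorted(
        (r for r in records if r.defined), key=lambda r: (r.gs, r.gene_id)
    )
    sig_ids: set[str] = set()
    cutoff: float | None = None
    n = len(defined)
    if n == 0:
        logger.warning("no defined GAD scores; nothing to call")
    elif n < params.min_genes:
        logger.warning(
            "only %d defined scores (< %d); applying the Gs floor rule only",
            n,
            params.min_genes,
        )
        sig_ids = {r.gene_id for r in defined if r.gs > params.score_floor}
        cutoff = params.score_floor
    else:
        scores = np.array([r.gs for r in defined])
        lo, hi = float(scores[0]), float(scores[-1])
        if hi == lo:
            logger.warning("degenerate flat score curve; no sig-GADs called")
        else:
            x = np.arange(n) / (n - 1)
            y = (scores - lo) / (hi - lo)
            cut_idx = int(np.argmin(y - x))
            cutoff = float(scores[cut_idx])
            sig_ids = {
                r.gene_id
                for rank, r in enumerate(defined)
                if rank > cut_idx and r.gs > params.score_floor
            }
    out = [replace(r, sig=r.gene_id in sig_ids) for r in records]
    return out, cutoff


def compare_gad_scores(
    records_a: list[GadRecord] | list[list[GadRecord]],
    records_b: list[GadRecord] | list[list[GadRecord]],
) -> pd.DataFrame:
    """Per-gene GAD score comparison between two conditions.

    Each argument is either one record list or a list of replicate record
    lists.  Only genes defined in every replicate of both conditions are
    compared.  Columns: gene_id, gs_a, gs_b (replicate means), delta_gs,
    and — when both sides have >= 2 replicates — a per-gene two-sided
    Wilcoxon rank-sum p-value.
    """

    def as_groups(x):
        return [x] if x and isinstance(x[0], GadRecord) else list(x)

    ga, gb = as_groups(records_a), as_groups(records_b)

    def defined_maps(group):
        return [{r.gene_id: r.gs for r in rep if r.defined} for rep in group]

    ma, mb = defined_maps(ga), defined_maps(gb)
    shared = set.intersection(*(set(m) for m in ma + mb)) if ma and mb else set()
    if not shared:
        raise ValueError("no gene is defined in both conditions")

    rows = []
    with_p = len(ma) >= 2 and len(mb) >= 2
    for gid in sorted(shared):
        va = [m[gid] for m in ma]
        vb = [m[gid] for m in mb]
        row = {
            "gene_id": gid,
            "gs_a": float(np.mean(va)),
            "gs_b": float(np.mean(vb)),
        }
        row["delta_gs"] = row["gs_b"] - row["gs_a"]
        if with_p:
            row["p"] = ranksum(va, vb).p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_genes_bed(path) -> list[GeneModel]:
    """Read gene models from BED6 (or BED4) with 0-based half-open intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = []
    for row in df.itertuples(index=False):
        strand = str(row[5]) if len(row) > 5 else "."
        genes.append(
            GeneModel(
                gene_id=str(row[3]),
                chrom=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=strand,
            )
        )
    return genes


def write_genes_bed(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "name": [g.gene_id for g in genes],
            "score": 0,
            "strand": [g.strand for g in genes],
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def records_to_frame(
    records: list[GadRecord], genes: list[GeneModel] | None = None
) -> pd.DataFrame:
    """Tabulate GAD records (optionally joined with gene coordinates)."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "n_bins": [r.n_bins for r in records],
            "G": [r.g for r in records],
            "Gu": [r.gu for r in records],
            "Gd": [r.gd for r in records],
            "Gs": [r.gs for r in records],
            "eligible": [r.eligible for r in records],
            "undefined_reason": [r.undefined_reason or "" for r in records],
            "sig": [r.sig for r in records],
        }
    )
    if genes is not None:
        gdf = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "chrom": [g.chrom for g in genes],
                "start": [g.start for g in genes],
                "end": [g.end for g in genes],
            }
        )
        df = gdf.merge(df, on="gene_id", how="right")
    return df
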