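"""Synthetic multilayer networks and expression matrices with known truth.

The network generator plants an association module — a subset of lncRNAs
densely connected (probability ``p_in``) to a subset of seed AS genes in
the bipartite co-expression and epigenetic layers, and a denser block among
the seed genes in the PPI layer — against sparse Erdős–Rényi background at
``p_bg``. The expression generator draws log-normal gene abundances, splits
them over isoforms via Dirichlet-distributed isoform fractions whose tumor
means are shifted by a planted dIF for switched isoforms, and couples
lncRNA profiles to target genes through a shared latent Gaussian factor so
the expected Pearson correlation equals the planted rho. Everything is
deterministic given the rng seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .events import IsoformAnnotation
from .isoform import ExpressionMatrix
from .network import Layer, MultiGraph, NodeMeta, build_multigraph

DEFAULT_CONCENTRATION = 5.0


@dataclass
class NetworkTruth:
    planted_lnc: set[str]
    planted_genes: set[str]
    params: dict = field(default_factory=dict)


@dataclass
class ExpressionTruth:
    switched_isoforms: dict[str, float]  # isoform id -> planted dIF
    correlated_pairs: dict[tuple[str, str], float]  # (lnc, gene) -> planted rho
    params: dict = field(default_factory=dict)


def _bipartite_edges(
    rng: np.random.Generator,
    left: Sequence[str],
    right: Sequence[str],
    p_bg: float,
    planted_left: Sequence[str],
    planted_right: Sequence[str],
    p_in: float,
) -> dict[tuple[str, str], float]:
    mask = rng.random((len(left), len(right))) < p_bg
    pl = set(planted_left)
    pr = set(planted_right)
    li = [i for i, u in enumerate(left) if u in pl]
    ri = [j for j, v in enumerate(right) if v in pr]
    if li and ri:
        sub = rng.random((len(li), len(ri))) < p_in
        mask[np.ix_(li, ri)] = sub
    edges: dict[tuple[str, str], float] = {}
    ii, jj = np.nonzero(mask)
    for i, j in zip(ii, jj):
        u, v = left[i], right[j]
        edges[(u, v) if u < v else (v, u)] = 1.0
    return edges


def gen_multilayer(
    n_lnc: int = 200,
    m_gene: int = 300,
    n_planted_lnc: int = 20,
    n_seed_genes: int = 30,
    p_in: float = 0.3,
    p_bg: float = 0.01,
    rng_seed: int | None = None,
) -> tuple[MultiGraph, NetworkTruth]:
    """Three evidence layers with a planted lncRNA–AS-gene module."""
    if n_planted_lnc > n_lnc or n_seed_genes > m_gene:
        raise ValueError("planted sets cannot exceed the node universe")
    if not (0.0 <= p_bg <= 1.0 and 0.0 <= p_in <= 1.0):
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    lnc_ids = [f"L{i:04d}" for i in range(n_lnc)]
    gene_ids = [f"G{i:04d}" for i in range(m_gene)]
    planted_lnc = sorted(rng.choice(lnc_ids, size=n_planted_lnc, replace=False))
    planted_genes = sorted(rng.choice(gene_ids, size=n_seed_genes, replace=False))

    coexpr = Layer(
        "coexpression",
        _bipartite_edges(rng, lnc_ids, gene_ids, p_bg, planted_lnc, planted_genes, p_in),
    )
    epi = Layer(
        "epigenetic",
        _bipartite_edges(rng, lnc_ids, gene_ids, p_bg, planted_lnc, planted_genes, p_in),
    )
    # gene-gene PPI: sparse background plus a denser block among seed genes
    gmask = rng.random((m_gene, m_gene)) < p_bg
    gi = [i for i, g in enumerate(gene_ids) if g in set(planted_genes)]
    gmask[np.ix_(gi, gi)] = rng.random((len(gi), len(gi))) < p_in
    ppi_edges: dict[tuple[str, str], float] = {}
    ii, jj = np.nonzero(np.triu(gmask, k=1))
    for i, j in zip(ii, jj):
        u, v = gene_ids[i], gene_ids[j]
        ppi_edges[(u, v) if u < v else (v, u)] = 1.0
    ppi = Layer("ppi", ppi_edges)

    nodes = [NodeMeta(i, "lncRNA") for i in lnc_ids] + [
        NodeMeta(g, "AS_gene") for g in gene_ids
    ]
    mg = build_multigraph([coexpr, epi, ppi], nodes)
    truth = NetworkTruth(
        planted_lnc=set(planted_lnc),
        planted_genes=set(planted_genes),
        params=dict(
            n_lnc=n_lnc,
            m_gene=m_gene,
            n_planted_lnc=n_planted_lnc,
            n_seed_genes=n_seed_genes,
            p_in=p_in,
            p_bg=p_bg,
            rng_seed=rng_seed,
        ),
    )
    return mg, truth


def concentration_for_if_sd(sd: float, mean_if: float = 0.5) -> float:
    """Dirichlet concentration giving a marginal IF standard deviation ``sd``."""
    if not (0 < sd**2 < mean_if * (1 - mean_if)):
        raise ValueError("sd incompatible with a Beta-distributed fraction")
    return mean_if * (1 - mean_if) / sd**2 - 1.0


def _exon_template(gene_index: int, variant: str) -> tuple[tuple[str, int, int], ...]:
    """Three-exon reference or a variant structure for one synthetic gene."""
    off = 10_000 * gene_index
    ref = ((100, 200), (300, 400), (500, 600))
    structures = {
        "ref": ref,
        "ES": ((100, 200), (500, 600)),
        "IR": ((100, 400), (500, 600)),
        "A3": ((100, 200), (330, 400), (500, 600)),
        "A5": ((100, 200), (300, 430), (500, 600)),
        "ATSS": ((140, 200), (300, 400), (500, 600)),
        "ATTS": ((100, 200), (300, 400), (500, 560)),
        "MEE": ((100, 200), (430, 470), (500, 600)),
    }
    exons = structures[variant]
    return tuple(("chrS", s + off, e + off) for s, e in exons)


def gen_expression(
    n_genes: int = 60,
    n_switch: int = 20,
    n_lnc: int = 30,
    n_corr_pairs: int = 10,
    samples_per_condition: int = 50,
    dif: float = 0.3,
    rho: float = 0.9,
    concentration: float = DEFAULT_CONCENTRATION,
    event_type: str = "ES",
    log_mean: float = 3.0,
    log_sd: float = 0.5,
    rng_seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict[str, IsoformAnnotation], ExpressionTruth]:
    """Expression with planted isoform switches and lncRNA–gene correlations.

    Every gene carries two isoforms with base mean IF (0.5, 0.5); for the
    first ``n_switch`` genes, isoform 1's tumor mean IF is shifted by
    ``dif`` (its sibling compensates). The first ``n_corr_pairs`` lncRNAs
    are coupled to target genes at correlation ``rho`` on the log scale via
    target = sqrt(rho)*z + sqrt(1-rho)*eps. Returns the isoform expression
    matrix, a gene-level lncRNA expression matrix, exon annotations in which
    each switched isoform differs from its reference by ``event_type``, and
    the ground truth.
    """
    if n_switch > n_genes or n_corr_pairs > min(n_lnc, n_genes):
        raise ValueError("planted counts exceed the universe")
    base_if = 0.5
    if not (0.0 <= base_if + dif <= 1.0):
        raise ValueError(f"planted dIF {dif} pushes isoform fraction outside [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_samp = 2 * samples_per_condition
    sample_ids = [f"T{i:03d}" for i in range(samples_per_condition)] + [
        f"N{i:03d}" for i in range(samples_per_condition)
    ]
    condition = pd.Series(
        ["tumor"] * samples_per_condition + ["normal"] * samples_per_condition,
        index=sample_ids,
        name="condition",
    )
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    lnc_ids = [f"L{i:04d}" for i in range(n_lnc)]

    # latent factors and correlated lncRNA profiles (log scale)
    z = rng.standard_normal((n_genes, n_samp))
    lz = rng.standard_normal((n_lnc, n_samp))
    corr_pairs: dict[tuple[str, str], float] = {}
    for k in range(n_corr_pairs):
        lz[k] = np.sqrt(rho) * z[k] + np.sqrt(1.0 - rho) * rng.standard_normal(n_samp)
        corr_pairs[(lnc_ids[k], gene_ids[k])] = rho
    gene_expr = np.exp(log_mean + log_sd * z)
    lnc_expr = pd.DataFrame(
        np.exp(log_mean + log_sd * lz), index=lnc_ids, columns=sample_ids
    )

    # isoform fractions: Dirichlet around condition-specific mean IF
    iso_rows = []
    iso_ids: list[str] = []
    iso_gene: list[str] = []
    switched: dict[str, float] = {}
    tumor_mask = (condition == "tumor").to_numpy()
    for gi, gid in enumerate(gene_ids):
        iso1, iso2 = f"{gid}.1", f"{gid}.2"
        planted = gi < n_switch
        mean_n = np.array([base_if, 1 - base_if])
        mean_t = np.array([base_if + dif, 1 - base_if - dif]) if planted else mean_n
        fracs = np.empty((2, n_samp))
        for s in range(n_samp):
            m = mean_t if tumor_mask[s] else mean_n
            alpha = np.maximum(concentration * m, 1e-3)
            fracs[:, s] = rng.dirichlet(alpha)
        iso_rows.append(fracs * gene_expr[gi])
        iso_ids += [iso1, iso2]
        iso_gene += [gid, gid]
        if planted:
            switched[iso1] = dif

    values = pd.DataFrame(
        np.vstack(iso_rows), index=iso_ids, columns=sample_ids
    )
    iso2gene = pd.Series(iso_gene, index=iso_ids, name="gene")
    expr = ExpressionMatrix(values=values, condition=condition, iso2gene=iso2gene)

    annotations: dict[str, IsoformAnnotation] = {}
    for gi, gid in enumerate(gene_ids):
        planted = gi < n_switch
        annotations[f"{gid}.2"] = IsoformAnnotation(
            f"{gid}.2", gid, "+", _exon_template(gi, "ref")
        )
        if planted:
            exons = _exon_template(gi, event_type)
        else:
            # unplanted sibling: harmless alternative termination
            exons = _exon_template(gi, "ATTS")
        annotations[f"{gid}.1"] = IsoformAnnotation(f"{gid}.1", gid, "+", exons)

    truth = ExpressionTruth(
        switched_isoforms=switched,
        correlated_pairs=corr_pairs,
        params=dict(
            n_genes=n_genes,
            n_switch=n_switch,
            n_lnc=n_lnc,
            n_corr_pairs=n_corr_pairs,
            samples_per_condition=samples_per_condition,
            dif=dif,
            rho=rho,
            concentration=concentration,
            event_type=event_type,
            rng_seed=rng_seed,
        ),
    )
    return expr, lnc_expr, annotations, truth


def gene_level_expression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Sum isoform abundances to gene level (targets for co-expression)."""
    return expr.values.groupby(expr.gene_of(), sort=False).sum()
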