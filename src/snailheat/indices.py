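"""Within-population diversity and between-population divergence indices.

Three indices summarize population structure from haplotype data:

* nucleotide diversity pi — the mean K2P-corrected per-site distance over all
  individual pairs within a population, with a standard deviation from the
  Nei (1987)-style total variance (sampling plus stochastic terms) or,
  optionally, the plain sample SD of the pairwise distances;
* Nei's pairwise fixation index F_ST in its pooled-frequency (G_ST-type)
  form, from haplotype frequency vectors of two populations;
* Morisita-Horn haplotype divergence H_MH = 1 - C_MH, treating haplotypes as
  species and populations as communities.

Both divergence indices depend only on haplotype relative frequencies and lie
in [0, 1].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .haplotypes import AlignedSequenceSet, HaplotypeTable, k2p_distance


@dataclass(frozen=True)
class DiversityEstimate:
    """Nucleotide diversity of one population (substitutions/site)."""

    population_id: str
    pi: float
    sd: float
    n: int


def nucleotide_diversity(
    seqs: AlignedSequenceSet,
    population_id: str | None = None,
    sd_estimator: str = "nei",
) -> DiversityEstimate:
    """Mean pairwise K2P distance within one population, with SD.

    ``sd_estimator``:

    * ``"nei"`` (default): square root of the total variance of pi,
      Var(pi) = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2,
      the estimator used by standard population-genetic software;
    * ``"sample"``: sample SD of the n(n-1)/2 pairwise distances.
    """
    recs = seqs.records
    if population_id is not None:
        recs = [r for r in recs if r.population_id == population_id]
    else:
        pops = {r.population_id for r in recs}
        if len(pops) != 1:
            raise ValueError(
                "sequence set spans several populations; pass population_id"
            )
        population_id = recs[0].population_id
    n = len(recs)
    if n < 2:
        raise ValueError(
            f"nucleotide diversity undefined for population {population_id!r} "
            f"with n={n} (< 2)"
        )
    dists = [
        k2p_distance(a.sequence, b.sequence)
        for a, b in itertools.combinations(recs, 2)
    ]
    pi = float(np.mean(dists))
    if sd_estimator == "nei":
        L = seqs.length
        var = (n + 1) / (3 * (n - 1) * L) * pi + (
            2 * (n * n + n + 3) / (9 * n * (n - 1))
        ) * pi * pi
        sd = math.sqrt(var)
    elif sd_estimator == "sample":
        sd = float(np.std(dists, ddof=1)) if len(dists) > 1 else 0.0
    else:
        raise ValueError(f"unknown sd_estimator {sd_estimator!r}")
    if pi == 0.0:
        sd = 0.0
    return DiversityEstimate(population_id, pi, sd, n)


def _freqs(counts: np.ndarray, name: str) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1:
        raise ValueError(f"{name} must be a 1-D count vector")
    if (counts < 0).any():
        raise ValueError(f"{name} has negative counts")
    tot = counts.sum()
    if tot <= 0:
        raise ValueError(f"{name} has zero total count")
    return counts / tot


def nei_pairwise_fst(counts_a, counts_b) -> float:
    """Nei pooled-frequency fixation index between two haplotype count vectors.

    F_ST = (H_T - H_S) / H_T with H_S = 1 - (sum p^2 + sum q^2)/2 and
    H_T = 1 - sum pbar^2 where pbar = (p + q)/2.  Defined as 0 when H_T = 0
    (both populations fixed for the same haplotype).
    """
    p = _freqs(counts_a, "counts_a")
    q = _freqs(counts_b, "counts_b")
    if p.shape != q.shape:
        raise ValueError("count vectors must index the same haplotypes")
    hs = 1.0 - (np.sum(p**2) + np.sum(q**2)) / 2.0
    pbar = (p + q) / 2.0
    ht = 1.0 - np.sum(pbar**2)
    if ht == 0.0:
        return 0.0
    return float((ht - hs) / ht)


def morisita_horn_divergence(counts_x, counts_y) -> float:
    """1 - Morisita-Horn overlap of two haplotype compositions.

    C_MH = 2 sum(x_i y_i) / ((d_x + d_y) X Y), d_x = sum x_i^2 / X^2; the
    divergence is 0 for proportional compositions and 1 for disjoint ones.
    """
    x = np.asarray(counts_x, dtype=float)
    y = np.asarray(counts_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must index the same haplotypes")
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("count vectors must have positive totals")
    dx = np.sum(x**2) / X**2
    dy = np.sum(y**2) / Y**2
    c = 2.0 * np.sum(x * y) / ((dx + dy) * X * Y)
    return float(1.0 - c)


def divergence_matrix(haps: HaplotypeTable, index_kind: str) -> DistanceMatrix:
    """Pairwise divergence matrix (``"FST"`` or ``"MorisitaHorn"``) over populations."""
    fn = {"FST": nei_pairwise_fst, "MorisitaHorn": morisita_horn_divergence}[
        index_kind
    ]
    pops = haps.population_ids
    n = len(pops)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = fn(
                haps.counts.loc[pops[i]].to_numpy(),
                haps.counts.loc[pops[j]].to_numpy(),
            )
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, pops)


def index_table(
    haps: HaplotypeTable,
    seqs: AlignedSequenceSet,
    sd_estimator: str = "nei",
) -> tuple[list[DiversityEstimate], DistanceMatrix, DistanceMatrix]:
    """All three indices: per-population pi, F_ST matrix, H_MH matrix."""
    if set(haps.population_ids) != set(seqs.population_ids):
        raise ValueError("haplotype table and sequence set disagree on populations")
    diversity = [
        nucleotide_diversity(seqs, pop, sd_estimator=sd_estimator)
        for pop in haps.population_ids
    ]
    fst = divergence_matrix(haps, "FST")
    hmh = divergence_matrix(haps, "MorisitaHorn")
    return diversity, fst, hmh


def combined_table(
    diversity: list[DiversityEstimate],
    fst: DistanceMatrix,
    hmh: DistanceMatrix,
) -> pd.DataFrame:
    """Square report table: pi +/- SD on the diagonal, H_MH above, F_ST below.

    Printed precision: 4 decimals for pi, 3 for F_ST, 2 for H_MH.
    """
    pops = list(fst.ids)
    div = {d.population_id: d for d in diversity}
    out = pd.DataFrame("", index=pops, columns=pops, dtype=object)
    for i, a in enumerate(pops):
        for j, b in enumerate(pops):
            if i == j:
                d = div[a]
                out.iloc[i, j] = f"{d.pi:.4f}±{d.sd:.4f}"
            elif i < j:
                out.iloc[i, j] = f"{hmh[a, b]:.2f}"
            else:
                out.iloc[i, j] = f"{fst[a, b]:.3f}"
    return out


def tidy_divergence(fst: DistanceMatrix, hmh: DistanceMatrix) -> pd.DataFrame:
    """Long-format table ``pop_a,pop_b,index,value`` over unordered pairs."""
    rows = []
    for name, dm in (("FST", fst), ("MorisitaHorn", hmh)):
        ids = list(dm.ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                rows.append({"pop_a": a, "pop_b": b, "index": name,
                             "value": dm[a, b]})
    return pd.DataFrame(rows)
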