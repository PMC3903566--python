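"""Aligned COI sequences, haplotype collapsing, and Kimura 2-parameter distances.

The genetic substrate of the pipeline is a set of pre-aligned, equal-length
mitochondrial COI sequences with a population label per individual.  Sequences
are collapsed into haplotypes (distinct sequence variants), and pairwise
divergence between sequences is measured with the Kimura 2-parameter (K2P)
model, which corrects the raw mismatch proportion while distinguishing
transitions (A<->G, C<->T) from transversions.

Sequences are assumed indel-free over a fixed window (a protein-coding
fragment); gaps and ambiguity codes are excluded site-wise from distance
computations ("pairwise deletion").
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

#: Unambiguous nucleotide alphabet used for site comparisons.
UNAMBIGUOUS = frozenset("ACGT")

#: Transition pairs under the K2P model (purine<->purine, pyrimidine<->pyrimidine).
_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


class SaturationError(ValueError):
    """K2P distance is undefined: a logarithm argument fell to or below zero."""


@dataclass(frozen=True)
class SequenceRecord:
    sequence_id: str
    population_id: str
    sequence: str


@dataclass
class AlignedSequenceSet:
    """Equal-length aligned DNA sequences with population assignments.

    Invariants: all sequences share ``length`` sites, sequence ids are unique,
    and at least one population is present.
    """

    records: list[SequenceRecord]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("AlignedSequenceSet requires at least one record")
        ids = [r.sequence_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            offenders = sorted(
                r.sequence_id
                for r in self.records
                if len(r.sequence) != len(self.records[0].sequence)
            )
            raise ValueError(
                "sequences are not all the same length; offending ids "
                f"(relative to first record): {offenders}"
            )
        bad = [
            r.sequence_id
            for r in self.records
            if set(r.sequence) - set("ACGTN-")
        ]
        if bad:
            raise ValueError(f"non-DNA characters in sequences: {bad}")
        object.__setattr__(self, "length", lengths.pop())

    @property
    def population_ids(self) -> list[str]:
        """Distinct population ids in order of first appearance."""
        seen: OrderedDict[str, None] = OrderedDict()
        for r in self.records:
            seen.setdefault(r.population_id, None)
        return list(seen)

    def subset_population(self, population_id: str) -> "AlignedSequenceSet":
        recs = [r for r in self.records if r.population_id == population_id]
        if not recs:
            raise ValueError(f"no records for population {population_id!r}")
        return AlignedSequenceSet(recs)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HaplotypeTable:
    """Distinct haplotype sequences and a populations x haplotypes count matrix.

    ``counts`` is a DataFrame indexed by population id with one column per
    haplotype id (H1, H2, ... in order of first appearance in the input).
    """

    haplotype_sequences: list[str]
    counts: pd.DataFrame
    population_ids: list[str]

    @property
    def haplotype_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_sequences)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def global_frequencies(self) -> pd.Series:
        tot = self.total_counts()
        return tot / tot.sum()

    def variable_sites(self) -> list[int]:
        """0-based alignment columns at which haplotypes differ (ignoring N/-)."""
        seqs = self.haplotype_sequences
        sites = []
        for j in range(len(seqs[0])):
            col = {s[j] for s in seqs} & UNAMBIGUOUS
            if len(col) > 1:
                sites.append(j)
        return sites

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path, index_label="population_id")


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column ``sequence_id,population_id`` CSV/TSV (header required)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"population map {path} must have at least 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_fasta_with_populations(
    fasta_path: str | Path,
    population_map: dict[str, str] | str | Path,
    trim_window: tuple[int, int] | None = None,
) -> AlignedSequenceSet:
    """Read an aligned FASTA plus a sequence->population map.

    Parameters
    ----------
    fasta_path:
        Multi-record FASTA (wrapped or unwrapped lines).
    population_map:
        Mapping of sequence id to population id, or a path to a 2-column
        CSV/TSV with a header.
    trim_window:
        Optional ``(start, stop)`` 0-based half-open window applied to every
        sequence before validation, for trimming to a common fragment.

    Raises
    ------
    ValueError
        Empty FASTA, a record id absent from the map, or unequal lengths.
    """
    if not isinstance(population_map, dict):
        population_map = read_population_map(population_map)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if trim_window is not None:
            seq = seq[trim_window[0]:trim_window[1]]
        if rec.id not in population_map:
            raise ValueError(
                f"sequence id {rec.id!r} missing from the population map"
            )
        records.append(SequenceRecord(rec.id, population_map[rec.id], seq))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    out = AlignedSequenceSet(records)
    per_pop = pd.Series([r.population_id for r in out.records]).value_counts()
    logger.info(
        "read %d sequences (%d sites) from %s; per-population counts: %s",
        len(out), out.length, fasta_path, per_pop.to_dict(),
    )
    return out


def _compatible(seq: str, hap: str) -> bool:
    """True if seq matches hap treating N (either side) as a wildcard."""
    return all(a == b or a == "N" or b == "N" for a, b in zip(seq, hap))


def collapse_haplotypes(
    seqs: AlignedSequenceSet, ambiguity_policy: str = "strict"
) -> HaplotypeTable:
    """Collapse aligned sequences into haplotypes.

    With ``strict`` policy haplotypes are exact string equivalence classes
    (N is a fifth symbol).  With ``match_N`` an N matches any base and each
    individual joins the first compatible haplotype in input order.
    """
    if ambiguity_policy not in ("strict", "match_N"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    hap_seqs: list[str] = []
    assignment: list[int] = []
    for rec in seqs.records:
        idx = None
        if ambiguity_policy == "strict":
            try:
                idx = hap_seqs.index(rec.sequence)
            except ValueError:
                idx = None
        else:
            for i, h in enumerate(hap_seqs):
                if _compatible(rec.sequence, h):
                    idx = i
                    break
        if idx is None:
            hap_seqs.append(rec.sequence)
            idx = len(hap_seqs) - 1
        assignment.append(idx)

    pops = seqs.population_ids
    hap_ids = [f"H{i + 1}" for i in range(len(hap_seqs))]
    counts = pd.DataFrame(0, index=pops, columns=hap_ids, dtype=int)
    for rec, idx in zip(seqs.records, assignment):
        counts.loc[rec.population_id, hap_ids[idx]] += 1
    assert int(counts.to_numpy().sum()) == len(seqs)
    return HaplotypeTable(hap_seqs, counts, pops)


def _site_counts(a: str, b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) under pairwise deletion."""
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            n += 1
            if x != y:
                if frozenset((x, y)) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    return n, ts, tv


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance in substitutions per site.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P and Q the transition and
    transversion proportions over sites where both sequences are unambiguous.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be the same length")
    n, ts, tv = _site_counts(a.upper(), b.upper())
    if n == 0:
        raise ValueError("no comparable (unambiguous) sites between sequences")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined/saturated (P={P:.4g}, Q={Q:.4g})"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_k2p_matrix(seqs: AlignedSequenceSet) -> DistanceMatrix:
    """Symmetric K2P distance matrix over all sequences in the set."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    n = len(seqs)
    ids = [r.sequence_id for r in seqs.records]
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = k2p_distance(seqs.records[i].sequence, seqs.records[j].sequence)
            except ValueError as exc:
                raise type(exc)(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids)


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square CSV with labels in the first row and column."""
    dm.to_data_frame().to_csv(path, index_label="")
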