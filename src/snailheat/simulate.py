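"""Synthetic sequence and physiology data with planted ground truth.

The generator emulates the statistical structure the analysis assumes, so
every stage of the pipeline can be exercised without external data:

* **Sequences** — 7 populations x 20 aligned 700 bp COI sequences drawn from
  6 haplotypes that differ at <= 7 positions (> 99% of sites shared), all
  within a few single mutational steps of a hub haplotype (so the parsimony
  network is a single component).  Two dominant haplotypes carry ~66% and
  ~19% of all sequences.  Per-population haplotype frequencies are
  Dirichlet-jittered around base frequencies; one population is monomorphic
  (pi = 0 downstream) and one is divergent, with a shifted frequency profile
  dominated by an otherwise-rare haplotype (elevated F_ST and H_MH against
  every other population).  A frequency-level model suffices because the
  downstream indices consume only haplotype counts.

* **Physiology** — per population x temperature, individual Hsp70 levels
  around a strategy-specific unimodal temperature profile peaking at
  38-40 °C, and 1-5 histology scores from a latent damage curve rising with
  temperature.  Three archetypal heat-response strategies are planted:
  ``moderate`` (peak induction 125-145% of control), ``high`` (155-195%),
  and ``flat`` (~104% peak, with cellular condition holding to 40 °C and
  collapsing sharply above — the divergent population's profile).  Calcium
  cells are planted as slightly more heat resistant than digestive cells at
  and above 40 °C.

Everything is driven by one integer seed; the same seed reproduces the same
datasets byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .haplotypes import AlignedSequenceSet, SequenceRecord

BASES = np.array(list("ACGT"))

#: Transition partner of each base (used so planted mutations are transitions,
#: keeping K2P distances in the low-divergence regime typical of COI data).
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic datasets (defaults = the
    emulated study conditions)."""

    seed: int = 0
    n_populations: int = 7
    n_seq_per_pop: int = 20
    seq_length: int = 700
    n_haplotypes: int = 6
    #: target global haplotype frequencies (dominant 66%, second 19%,
    #: remainder split over the minor haplotypes)
    global_haplotype_freqs: tuple[float, ...] = (
        0.66, 0.19, 0.0375, 0.0375, 0.0375, 0.0375
    )
    max_variable_sites: int = 7
    #: Dirichlet concentration scaling for per-population frequency jitter
    dirichlet_concentration: float = 150.0
    monomorphic_populations: tuple[str, ...] = ("7",)
    divergent_populations: tuple[str, ...] = ("4",)
    #: frequency profile of divergent populations (mass moved onto H4)
    divergent_freqs: tuple[float, ...] = (0.15, 0.05, 0.025, 0.70, 0.0375, 0.0375)
    #: base frequencies of the remaining ("regular") populations
    regular_freqs: tuple[float, ...] = (0.66, 0.24, 0.03, 0.01, 0.03, 0.03)
    strategy_map: dict[str, str] = field(default_factory=lambda: {
        "1": "moderate", "2": "moderate", "5": "moderate",
        "3": "high", "6": "high", "7": "high",
        "4": "flat",
    })
    temperatures: tuple[int, ...] = (25, 33, 38, 40, 43, 45, 48)
    n_hsp70: int = 10
    n_histology: int = 8
    #: relative SD of individual Hsp70 levels around the group mean
    hsp70_noise_sd: float = 0.12
    #: SD of the latent damage variable before discretization to 1-5
    histology_noise_sd: float = 0.6
    #: Hsp70 percent-of-control profiles per strategy (25 °C is 100 by
    #: definition; peaks at 38-40 °C, declining at >= 43 °C)
    hsp70_profiles: dict[str, dict[int, float]] = field(default_factory=lambda: {
        "moderate": {25: 100, 33: 106, 38: 125, 40: 145, 43: 110, 45: 90, 48: 80},
        "high":     {25: 100, 33: 110, 38: 145, 40: 165, 43: 115, 45: 92, 48: 82},
        "flat":     {25: 100, 33: 101, 38: 103, 40: 104, 43: 95, 45: 85, 48: 75},
    })
    #: latent MAV curves per strategy and tissue (means of the 1-5 scores);
    #: controls sit near category 1-2 and 48 °C groups near 4-5; the flat
    #: strategy holds a good condition to 40 °C then collapses; calcium cells
    #: are planted as more resistant than digestive cells at >= 40 °C
    mav_curves: dict[str, dict[str, dict[int, float]]] = field(
        default_factory=lambda: {
            "moderate": {
                "tubule":    {25: 1.4, 33: 2.0, 38: 2.3, 40: 2.7, 43: 3.2, 45: 3.8, 48: 4.4},
                "digestive": {25: 1.4, 33: 2.0, 38: 2.4, 40: 2.9, 43: 3.4, 45: 4.0, 48: 4.6},
                "calcium":   {25: 1.6, 33: 2.1, 38: 2.3, 40: 2.5, 43: 2.9, 45: 3.5, 48: 4.3},
            },
            "high": {
                "tubule":    {25: 1.4, 33: 2.1, 38: 2.4, 40: 2.8, 43: 3.3, 45: 3.9, 48: 4.5},
                "digestive": {25: 1.4, 33: 2.1, 38: 2.5, 40: 3.0, 43: 3.5, 45: 4.1, 48: 4.7},
                "calcium":   {25: 1.6, 33: 2.2, 38: 2.4, 40: 2.6, 43: 3.0, 45: 3.6, 48: 4.4},
            },
            "flat": {
                "tubule":    {25: 1.3, 33: 1.5, 38: 1.6, 40: 1.8, 43: 3.9, 45: 4.3, 48: 4.7},
                "digestive": {25: 1.3, 33: 1.5, 38: 1.7, 40: 1.8, 43: 4.1, 45: 4.5, 48: 4.9},
                "calcium":   {25: 1.5, 33: 1.7, 38: 1.8, 40: 1.9, 43: 3.8, 45: 4.2, 48: 4.6},
            },
        }
    )

    def __post_init__(self) -> None:
        if abs(sum(self.global_haplotype_freqs) - 1.0) > 1e-9:
            raise ValueError("global haplotype frequencies must sum to 1")
        if len(self.global_haplotype_freqs) != self.n_haplotypes:
            raise ValueError("one global frequency per haplotype is required")
        if self.max_variable_sites / self.seq_length > 0.01:
            raise ValueError(
                "max_variable_sites must keep > 99% of sites invariant"
            )
        pops = self.population_ids
        missing = [p for p in pops if p not in self.strategy_map]
        if missing:
            raise ValueError(f"strategy_map does not cover populations {missing}")

    @property
    def population_ids(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_populations)]


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to each dataset."""

    haplotype_sequences: list[str] = field(default_factory=list)
    population_frequencies: dict[str, list[float]] = field(default_factory=dict)
    population_counts: dict[str, list[int]] = field(default_factory=dict)
    strategies: dict[str, str] = field(default_factory=dict)
    hsp70_means: dict[str, dict[int, float]] = field(default_factory=dict)
    mav_means: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def _build_haplotypes(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Hub haplotype plus single/double-step mutants at distinct sites."""
    ref = rng.choice(BASES, size=cfg.seq_length)
    sites = rng.choice(cfg.seq_length, size=cfg.max_variable_sites, replace=False)
    needed = cfg.n_haplotypes - 1
    if needed > cfg.max_variable_sites:
        raise ValueError(
            "more haplotypes requested than available variable sites"
        )
    haps = ["".join(ref)]
    site_iter = iter(sorted(int(s) for s in sites))
    for k in range(needed):
        mut = ref.copy()
        # haplotype H4 (index 3) sits two steps from the hub; others one step
        n_steps = 2 if k == 2 and cfg.max_variable_sites >= needed + 1 else 1
        for _ in range(n_steps):
            j = next(site_iter)
            mut[j] = _TRANSITION[str(mut[j])]
        haps.append("".join(mut))
    return haps


def _sample_counts(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-population haplotype counts (Dirichlet-multinomial with archetypes)."""
    pops = cfg.population_ids
    counts = pd.DataFrame(
        0, index=pops, columns=[f"H{i+1}" for i in range(cfg.n_haplotypes)],
        dtype=int,
    )
    for pop in pops:
        if pop in cfg.monomorphic_populations:
            counts.loc[pop, "H1"] = cfg.n_seq_per_pop
            continue
        base = (cfg.divergent_freqs if pop in cfg.divergent_populations
                else cfg.regular_freqs)
        alpha = np.maximum(np.asarray(base) * cfg.dirichlet_concentration, 1e-3)
        freqs = rng.dirichlet(alpha)
        counts.loc[pop] = rng.multinomial(cfg.n_seq_per_pop, freqs)
        # the two dominant haplotypes are present in every polymorphic
        # population: top up from the population's most common haplotype
        for h in ("H1", "H2"):
            if counts.loc[pop, h] == 0:
                donor = counts.loc[pop].idxmax()
                counts.loc[pop, donor] -= 1
                counts.loc[pop, h] += 1
    # every planted haplotype occurs at least once overall; monomorphic
    # populations never donate (their pi = 0 is a planted invariant)
    polymorphic = [p for p in pops if p not in cfg.monomorphic_populations]
    totals = counts.sum(axis=0)
    for h in counts.columns:
        if totals[h] == 0:
            donor_pop = counts.loc[polymorphic, "H1"].idxmax()
            counts.loc[donor_pop, "H1"] -= 1
            counts.loc[donor_pop, h] += 1
            totals = counts.sum(axis=0)
    return counts


def generate_sequences(
    cfg: SimulationConfig,
) -> tuple[AlignedSequenceSet, SyntheticTruth]:
    """Aligned sequence set with population labels plus the planted truth."""
    rng = np.random.default_rng(cfg.seed)
    haps = _build_haplotypes(cfg, rng)
    counts = _sample_counts(cfg, rng)
    records = []
    for pop in cfg.population_ids:
        k = 0
        for j, h in enumerate(counts.columns):
            for _ in range(int(counts.loc[pop, h])):
                k += 1
                records.append(
                    SequenceRecord(f"P{pop}_{k:02d}", pop, haps[j])
                )
    truth = SyntheticTruth(
        haplotype_sequences=haps,
        population_frequencies={
            p: (counts.loc[p] / counts.loc[p].sum()).tolist()
            for p in cfg.population_ids
        },
        population_counts={p: counts.loc[p].tolist() for p in cfg.population_ids},
        strategies=dict(cfg.strategy_map),
    )
    return AlignedSequenceSet(records), truth


def write_sequences(
    seqs: AlignedSequenceSet, fasta_path: str | Path, popmap_path: str | Path
) -> None:
    with open(fasta_path, "w") as fh:
        for r in seqs.records:
            fh.write(f">{r.sequence_id}\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i:i + 70] + "\n")
    pd.DataFrame(
        {"sequence_id": [r.sequence_id for r in seqs.records],
         "population_id": [r.population_id for r in seqs.records]}
    ).to_csv(popmap_path, index=False)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Gaussian draws re-sampled (then clipped) to stay non-negative."""
    out = rng.normal(mean, sd, size)
    for _ in range(10):
        neg = out < 0
        if not neg.any():
            break
        out[neg] = rng.normal(mean, sd, int(neg.sum()))
    return np.clip(out, 0.0, None)


def generate_physiology(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Tidy per-individual physiology table plus the planted truth.

    Hsp70 individual levels are truncated-at-zero Gaussians around the
    strategy profile (25 °C group mean 1.0 by construction); histology scores
    discretize a latent damage curve plus Gaussian noise into categories 1-5.
    """
    # physiology stream is decoupled from the sequence stream so either
    # dataset can be regenerated independently under the same seed
    rng = np.random.default_rng((cfg.seed, 1))
    truth = SyntheticTruth(strategies=dict(cfg.strategy_map))
    rows = []
    for pop in cfg.population_ids:
        strategy = cfg.strategy_map[pop]
        profile = cfg.hsp70_profiles[strategy]
        curves = cfg.mav_curves[strategy]
        truth.hsp70_means[pop] = {t: profile[t] / 100.0 for t in cfg.temperatures}
        truth.mav_means[pop] = {
            tissue: {t: curves[tissue][t] for t in cfg.temperatures}
            for tissue in curves
        }
        k = 0
        for t in cfg.temperatures:
            level = profile[t] / 100.0
            hsp_vals = _truncated_normal(
                rng, level, cfg.hsp70_noise_sd * level, cfg.n_hsp70
            )
            latent = {
                tissue: rng.normal(curves[tissue][t], cfg.histology_noise_sd,
                                   cfg.n_histology)
                for tissue in ("tubule", "digestive", "calcium")
            }
            n_ind = max(cfg.n_hsp70, cfg.n_histology)
            for i in range(n_ind):
                k += 1
                rows.append({
                    "individual_id": f"P{pop}_T{t}_{k:03d}",
                    "population_id": pop,
                    "temperature": t,
                    "hsp70_rel": round(float(hsp_vals[i]), 4)
                    if i < cfg.n_hsp70 else np.nan,
                    **{
                        f"{tissue}_score": int(
                            np.clip(np.rint(latent[tissue][i]), 1, 5)
                        ) if i < cfg.n_histology else np.nan
                        for tissue in ("tubule", "digestive", "calcium")
                    },
                })
    return pd.DataFrame(rows), truth
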