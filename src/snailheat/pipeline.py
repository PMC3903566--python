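"""End-to-end orchestration: sequences + physiology in, report tables out.

Stage order: haplotypes -> network -> indices -> ordination -> physiology ->
mrt.  Outputs are plain CSV/JSON for diff-ability; every numeric output file
carries a header comment with the configuration hash and seed, and reruns
with the same inputs and configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .haplotypes import (
    AlignedSequenceSet,
    collapse_haplotypes,
    read_fasta_with_populations,
)
from .indices import combined_table, index_table, tidy_divergence
from .mrt import (
    cross_validate,
    first_split_r2,
    fit_mrt,
    newick_topology,
    primary_split_correlations,
)
from .network import build_network, parsimony_connection_limit, write_network
from .ordination import pcoa, write_ordination
from .physiology import (
    anova_tukey,
    induction_table,
    read_physiology,
    significance_table,
    summarize,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("haplotypes", "network", "indices", "ordination", "physiology", "mrt")

#: upstream stages each stage depends on
_DEPS = {
    "haplotypes": (),
    "network": ("haplotypes",),
    "indices": ("haplotypes",),
    "ordination": ("indices",),
    "physiology": (),
    "mrt": ("ordination", "physiology"),
}


@dataclass
class PipelineConfig:
    fasta: str | Path
    popmap: str | Path
    physiology_csv: str | Path
    out_dir: str | Path
    seed: int = 0
    confidence: float = 0.95
    connection_limit: int | None = None
    ambiguity_policy: str = "strict"
    sd_estimator: str = "nei"
    hmh_axes: int = 3
    fst_axes: int = 2
    folds: int = 10
    reps: int = 1000
    standardize: bool = True
    cv_rule: str = "1se"
    mrt_temperatures: tuple[int, ...] = (25, 33, 40, 48)
    stages: tuple[str, ...] = ALL_STAGES

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed or a dependency was not run."""


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
               **to_csv_kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, **to_csv_kwargs)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns a manifest dict (also written as ``manifest.json``) listing the
    outputs, parameters, and seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = set(cfg.stages)
    for stage in enabled:
        for dep in _DEPS[stage]:
            if dep not in enabled:
                raise StageError(
                    f"stage {stage!r} requires stage {dep!r}, which is disabled"
                )

    results: dict = {}
    outputs: dict[str, str] = {}

    def _run(stage, fn):
        if stage not in enabled:
            return
        try:
            fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    seqs: AlignedSequenceSet | None = None

    def _haplotypes():
        nonlocal seqs
        seqs = read_fasta_with_populations(cfg.fasta, cfg.popmap)
        haps = collapse_haplotypes(seqs, cfg.ambiguity_policy)
        results["haplotypes"] = haps
        _write_csv(haps.counts, out / "haplotype_counts.csv", cfg,
                   index_label="population_id")
        outputs["haplotype_counts"] = "haplotype_counts.csv"

    def _network():
        haps = results["haplotypes"]
        limit = (cfg.connection_limit if cfg.connection_limit is not None
                 else parsimony_connection_limit(seqs.length, cfg.confidence))
        net = build_network(haps, limit)
        results["network"] = net
        write_network(net, str(out / "network"))
        summary = {
            "connection_limit_steps": limit,
            "confidence": cfg.confidence,
            "n_haplotypes": haps.n_haplotypes,
            "n_components": net.n_components,
            "components": net.components,
            "n_inferred_intermediates": len(net.intermediates),
        }
        with open(out / "network_components.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        outputs["network"] = "network_edges.csv"
        results["network_summary"] = summary

    def _indices():
        haps = results["haplotypes"]
        diversity, fst, hmh = index_table(haps, seqs,
                                          sd_estimator=cfg.sd_estimator)
        results["indices"] = (diversity, fst, hmh)
        _write_csv(combined_table(diversity, fst, hmh),
                   out / "genetic_indices_table.csv", cfg, index_label="")
        _write_csv(tidy_divergence(fst, hmh), out / "divergence_long.csv",
                   cfg, index=False)
        outputs["genetic_indices"] = "genetic_indices_table.csv"

    def _ordination():
        _, fst, hmh = results["indices"]
        ords = {
            "HMH": pcoa(hmh, cfg.hmh_axes),
            "FST": pcoa(fst, cfg.fst_axes),
        }
        results["ordination"] = ords
        for name, res in ords.items():
            write_ordination(res, out / f"pcoa_{name.lower()}",
                             prefix=f"{name}")
        outputs["ordination"] = "pcoa_hmh_coords.csv"

    def _physiology():
        phys = read_physiology(cfg.physiology_csv)
        results["physiology_raw"] = phys
        summary = summarize(phys)
        results["physiology"] = summary
        _write_csv(summary, out / "physiology_summary.csv", cfg, index=False)
        _write_csv(induction_table(phys), out / "max_induction.csv", cfg,
                   index=False)
        _write_csv(significance_table(phys), out / "significance.csv", cfg,
                   index=False)
        try:
            at40 = anova_tukey(phys, "hsp70_rel", temperature=40)
            results["anova_40C"] = at40
            letters = pd.DataFrame({
                "population_id": at40.groups,
                "letters": [at40.letters[g] for g in at40.groups],
            })
            letters.attrs["F"] = at40.f_statistic
            _write_csv(letters, out / "anova_tukey_40C.csv", cfg, index=False)
        except ValueError as exc:
            logger.warning("skipping 40 °C ANOVA: %s", exc)
        outputs["physiology_summary"] = "physiology_summary.csv"

    def _mrt():
        _, fst, hmh = results["indices"]
        diversity = results["indices"][0]
        ords = results["ordination"]
        summary = results["physiology"]
        pops = [d.population_id for d in diversity]
        X = pd.DataFrame(index=pops)
        X["pi"] = [d.pi for d in diversity]
        hmh_coords = ords["HMH"].to_frame("HMH")
        fst_coords = ords["FST"].to_frame("FST")
        X = X.join(hmh_coords).join(fst_coords)

        rows = []
        trees = {}
        for temp in cfg.mrt_temperatures:
            sub = summary[summary["temperature"] == temp].set_index(
                "population_id"
            )
            Y = sub.reindex(pops)[
                ["hsp70_mean", "mav_tubule", "mav_digestive", "mav_calcium"]
            ]
            if Y.isna().any().any():
                logger.warning("MRT at %d °C skipped: missing response cells",
                               temp)
                continue
            cv = cross_validate(
                X, Y, folds=cfg.folds, reps=cfg.reps, seed=cfg.seed,
                standardize=cfg.standardize, rule=cfg.cv_rule,
            )
            tree = fit_mrt(X, Y, standardize=cfg.standardize)
            trees[temp] = (tree, cv)
            if tree.root.is_leaf:
                rows.append({
                    "temperature": temp, "r2_first_split_pct": 0.0,
                    "cv_error": cv.error_for(cv.selected_size),
                    "selected_size": cv.selected_size,
                    "newick": newick_topology(tree),
                    "paper_style_topology": newick_topology(tree, paper_style=True),
                    "primary_variable": "", "signs": "",
                })
                continue
            signs = primary_split_correlations(tree, X, Y)
            sign_txt = "; ".join(
                f"{r.response} ({r.annotation})" for r in signs.itertuples()
            )
            rows.append({
                "temperature": temp,
                "r2_first_split_pct": round(100 * first_split_r2(tree), 1),
                "cv_error": round(cv.error_for(cv.selected_size), 3),
                "selected_size": cv.selected_size,
                "newick": newick_topology(tree),
                "paper_style_topology": newick_topology(tree, paper_style=True),
                "primary_variable": tree.root.split_variable,
                "signs": sign_txt,
            })
        results["mrt"] = trees
        _write_csv(pd.DataFrame(rows), out / "mrt_table.csv", cfg, index=False)
        outputs["mrt"] = "mrt_table.csv"

    for stage, fn in (
        ("haplotypes", _haplotypes), ("network", _network),
        ("indices", _indices), ("ordination", _ordination),
        ("physiology", _physiology), ("mrt", _mrt),
    ):
        _run(stage, fn)

    manifest = {
        "package": "snailheat",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "parameters": {k: str(v) for k, v in dataclasses.asdict(cfg).items()
                       if k != "out_dir"},
        "stages_run": [s for s in ALL_STAGES if s in enabled],
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results
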