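"""End-to-end orchestration: prep -> ML tree (+bootstrap) -> hypothesis
evaluation -> ancestral states -> key sites, from one flat configuration.

Every stage writes its outputs into the run directory and logs into a JSON
manifest (seed, versions, timings, per-stage status).  Stages communicate
only through declared files/objects, and any stage failure aborts the run
with the stage name and a machine-readable error record in the manifest.
"""
from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import MultipleAlignment, composition_homogeneity_test, ry_recode
from .acr import CharacterMatrix, backbone_tree, count_gains, fitch_acr, \
    opsin_character_matrix
from .keysites import compare_paralog_key_sites, translate_cds
from .reconcile import build_hypothesis_topologies, evaluate_hypotheses
from .search import bootstrap_support, ml_search
from .simulate import SimulationModel, compact_species_tree, simulate_gene_family
from .substmodel import GTRGamma
from .trees import write_tree

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "demo"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, error: Exception):
        super().__init__(f"stage {stage!r} failed: {error}")
        self.stage = stage
        self.record = {"stage": stage, "error_type": type(error).__name__,
                       "message": str(error)}


@dataclass
class RunConfig:
    """Flat key/value configuration for :func:`run_pipeline`."""
    alignment: str
    outdir: str
    seed: int = 0
    frame: int = 0
    ry3: bool = True
    lineage_map: Optional[str] = None          # 2-column TSV: taxon, tag
    outgroup: Tuple[str, ...] = ()
    character_matrix: Optional[str] = None     # TSV; default packaged matrix
    acr_clade: str = "Teleostei"
    keysite_pairs: Tuple[Tuple[str, str], ...] = ()
    translate_frame: Optional[int] = 0         # None = sequences are protein
    alpha_init: float = 0.5
    ncat: int = 4
    starts: int = 5
    bootstrap: int = 1000
    au_B: int = 10000
    au_alpha: float = 0.05
    optimize_model: str = "per_tree"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "keysite_pairs" in raw:
            raw["keysite_pairs"] = tuple(tuple(p) for p in raw["keysite_pairs"])
        if "outgroup" in raw:
            raw["outgroup"] = tuple(raw["outgroup"])
        return cls(**raw)

    def validate(self) -> None:
        for key in ("alignment", "lineage_map", "character_matrix"):
            val = getattr(self, key)
            if val is not None and key == "alignment" and not Path(val).exists():
                raise FileNotFoundError(f"{key} file not found: {val}")
            if key != "alignment" and val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key} file not found: {val}")


def _read_lineage_map(path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "tag"],
                     dtype=str, comment="#")
    return dict(zip(df["taxon"], df["tag"]))


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run every configured stage; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "package": "rhodups", "version": __version__,
        "python": platform.python_version(), "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }
    timings = manifest["stages"]

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as err:  # noqa: BLE001 - re-raised with context
                timings[name] = {"status": "failed",
                                 "error": {"type": type(err).__name__,
                                           "message": str(err)}}
                (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise PipelineError(name, err) from err
            timings[name] = {"status": "ok",
                             "seconds": round(time.perf_counter() - t0, 3)}
            return out
        return deco

    # -- stage 1: composition + recoding --------------------------------
    def _prep():
        aln = MultipleAlignment.from_fasta(config.alignment,
                                           frame_offset=config.frame)
        rows = []
        for pos in (1, 2, 3):
            rep = composition_homogeneity_test(aln, pos)
            rows.append({"codon_position": pos, "chi2": rep.chi2,
                         "df": rep.df, "p_value": rep.p_value,
                         "n_taxa": rep.counts.shape[0]})
        pd.DataFrame(rows).to_csv(outdir / "composition.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        used = ry_recode(aln) if config.ry3 else aln
        used.to_fasta(outdir / "prepared.fasta")
        return aln, used
    aln_raw, aln = stage("prep")(_prep)

    model = GTRGamma(alpha=config.alpha_init, ncat=config.ncat)

    # -- stage 2: ML tree + bootstrap ------------------------------------
    def _ml():
        best = ml_search(aln, model, n_starts=config.starts, seed=config.seed,
                         optimize_model=True)
        if config.bootstrap > 0:
            boot = bootstrap_support(aln, best.model, B=config.bootstrap,
                                     seed=config.seed, best=best)
            write_tree(boot.tree, outdir / "best_tree.nwk")
        else:
            write_tree(best.tree, outdir / "best_tree.nwk")
        with open(outdir / "best_tree.txt", "w") as fh:
            fh.write(f"# seed {config.seed}\nlnL\t{best.loglik:.6f}\n")
        return best
    best = stage("ml_tree")(_ml)

    # -- stage 3: hypothesis evaluation ----------------------------------
    report = None
    if config.lineage_map is not None:
        def _hyp():
            tag_map = _read_lineage_map(config.lineage_map)
            rep = evaluate_hypotheses(
                aln, best.model, build_hypothesis_topologies(), tag_map,
                outgroup=config.outgroup, n_starts=1, seed=config.seed,
                optimize_model=config.optimize_model, au_B=config.au_B,
                alpha=config.au_alpha)
            table = rep.table.copy()
            table["unrejected_au"] = table["au"] >= config.au_alpha
            table.to_csv(outdir / "hypotheses.tsv", sep="\t", index=False,
                         float_format="%.6g")
            return rep
        report = stage("hypotheses")(_hyp)

    # -- stage 4: ancestral states ---------------------------------------
    def _acr():
        cm = (CharacterMatrix.from_tsv(config.character_matrix)
              if config.character_matrix else opsin_character_matrix())
        tree = backbone_tree()
        rows = []
        with open(outdir / "acr_trees.nwk", "w") as fh:
            for char in cm.characters:
                res = fitch_acr(tree, cm.column(char))
                gains = None
                if "2" in res.states:
                    gains = count_gains(res, "1", "2", config.acr_clade)
                rows.append({"character": char, "min_changes": res.min_changes,
                             "gains_1_to_2_in_clade": gains})
                fh.write(res.annotated_newick())
        pd.DataFrame(rows).to_csv(outdir / "acr_summary.tsv", sep="\t",
                                  index=False)
        return rows
    acr_rows = stage("acr")(_acr)

    # -- stage 5: key sites ----------------------------------------------
    if config.keysite_pairs:
        def _keysites():
            frames = []
            for a, b in config.keysite_pairs:
                sa, sb = aln_raw.sequence(a), aln_raw.sequence(b)
                if config.translate_frame is not None:
                    sa = translate_cds(sa, config.translate_frame)
                    sb = translate_cds(sb, config.translate_frame)
                comp = compare_paralog_key_sites(sa, sb, labels=("seq_a", "seq_b"))
                comp.insert(0, "pair", f"{a}|{b}")
                frames.append(comp)
            pd.concat(frames).to_csv(outdir / "keysites.tsv", sep="\t",
                                     index=False)
            return frames
        stage("keysites")(_keysites)

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir()
                                 if p.name != "manifest.json")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def demo(outdir, seed: int = 0, sites: int = 996, scenario: str = "B6",
         au_B: int = 1000, bootstrap: int = 20) -> Dict[str, object]:
    """No-download demonstration run on simulated data.

    Simulates a gene family under the requested scenario (default B6, the
    best-supported history: a teleost-stem duplication followed by a
    clupeocephalan-stem duplication) with third-position compositional
    heterogeneity, writes the inputs into ``outdir`` and runs the full
    pipeline on them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .simulate import rhodopsin_root_sequence
    sim = SimulationModel(site_count=sites,
                          third_position_freqs=(0.15, 0.35, 0.15, 0.35),
                          root_sequence=rhodopsin_root_sequence(sites))
    truth, aln = simulate_gene_family(scenario, seed=seed,
                                      species_tree=compact_species_tree(),
                                      sim_model=sim)
    aln.to_fasta(outdir / "family.fasta")
    (outdir / "truth.json").write_text(truth.to_json())
    tag_map = {l: t for l, t in truth.tag_map.items() if t != "outgroup"}
    with open(outdir / "lineages.tsv", "w") as fh:
        for taxon, tag in sorted(tag_map.items()):
            fh.write(f"{taxon}\t{tag}\n")
    pairs = ()
    if {"Elops_dso", "Elops_fwo"} <= set(aln.ids):
        pairs = (("Elops_dso", "Elops_fwo"),)
    config = RunConfig(
        alignment=str(outdir / "family.fasta"),
        outdir=str(outdir), seed=seed,
        lineage_map=str(outdir / "lineages.tsv"),
        outgroup=tuple(truth.outgroup_taxa()),
        keysite_pairs=pairs, starts=2, bootstrap=bootstrap,
        au_B=au_B, optimize_model="shared")
    return run_pipeline(config)
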