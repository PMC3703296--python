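"""End-to-end orchestration: validation, the full results table, provenance.

``run_table`` reproduces the canonical layout of a phylogenetic-signal
analysis over acoustic traits: for every analysis group (the whole sample
plus each clade) and every trait, Moran's I and Geary's C on two
relatedness models (pairwise genetic distances and Abouheif proximities),
Blomberg's K on the BM variance-covariance matrix, and Mantel tests of the
multivariate trait distance — with the forward stepwise trait selection run
on the whole sample only and its winning subset re-evaluated within each
clade.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .audio import TRAIT_COLUMNS, read_metadata, read_wav, species_trait_table
from .matrices import SquareTaxonMatrix
from .pgls import size_correct, standardize
from .phylo import (
    abouheif_proximity,
    bm_vcv,
    distance_to_weights,
    pairwise_distance,
    proximity_to_dissimilarity,
    proximity_to_weights,
    prune_tree,
    read_fasta,
    read_tree,
    tip_labels,
)
from .signal_tests import (
    SignalTestResult,
    blombergs_k_mc,
    gearys_c_mc,
    mantel_mc,
    morans_i_mc,
)
from .stepwise import ForwardStepwiseMantel, euclidean_trait_distance

RESULT_COLUMNS = [
    "group",
    "trait",
    "test",
    "distance_model",
    "statistic",
    "expectation",
    "std_deviate",
    "p_mc",
    "stars",
    "n_perm",
    "seed",
]


def stars(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ValidationReport:
    """Species-id cross-check between metadata, tree and genetic data."""

    missing_in_tree: list[str] = field(default_factory=list)
    missing_in_genetic: list[str] = field(default_factory=list)
    extra_tree_tips: list[str] = field(default_factory=list)
    extra_genetic_taxa: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing_in_tree or self.missing_in_genetic)

    @property
    def prunable(self) -> bool:
        return bool(self.extra_tree_tips or self.extra_genetic_taxa)


def validate_inputs(
    species: Sequence[str],
    tree,
    genetic_taxa: Sequence[str] | None = None,
) -> ValidationReport:
    sp = set(species)
    tips = set(tip_labels(tree))
    rep = ValidationReport(
        missing_in_tree=sorted(sp - tips),
        extra_tree_tips=sorted(tips - sp),
    )
    if genetic_taxa is not None:
        gt = set(genetic_taxa)
        rep.missing_in_genetic = sorted(sp - gt)
        rep.extra_genetic_taxa = sorted(gt - sp)
    return rep


def _result_row(res: SignalTestResult, trait: str) -> dict:
    return {
        "group": res.group,
        "trait": trait,
        "test": res.test,
        "distance_model": res.distance_model,
        "statistic": res.statistic,
        "expectation": res.expectation,
        "std_deviate": res.std_deviate,
        "p_mc": res.p_mc,
        "stars": stars(res.p_mc),
        "n_perm": res.n_perm,
        "seed": res.seed,
    }


def run_table(
    traits: pd.DataFrame,
    tree,
    pairwise_D: SquareTaxonMatrix | None = None,
    trait_columns: Sequence[str] = tuple(TRAIT_COLUMNS),
    n_perm: int = 10_000,
    n_boot: int = 10_000,
    seed: int = 0,
    tests: Sequence[str] = ("moran", "geary", "blomberg_k", "mantel"),
    run_stepwise: bool = True,
    min_clade_size: int = 5,
    weight_scheme: str = "inverse",
    holm: bool = False,
) -> tuple[pd.DataFrame, dict | None, pd.DataFrame]:
    """Full cross of {trait, group, test, relatedness model}.

    Returns ``(results, stepwise_trace_dict, residuals)``. Whole-sample
    rows use residuals from a single PGLS per trait on the full tree;
    intra-clade rows use per-clade regressions on pruned trees, with
    within-clade standardization, and all pairwise structures recomputed on
    the clade subsets.
    """
    rng = np.random.default_rng(seed)

    def next_seed() -> int:
        return int(rng.integers(2**31))

    res_all = standardize(size_correct(traits, tree, "all"))
    res_clade = standardize(size_correct(traits, tree, "per_clade", min_clade_size=3))
    rows: list[dict] = []
    trace_dict = None
    selected: dict[str, list[str]] = {}

    groups = [("all", res_all)] + [
        (str(c), sub) for c, sub in res_clade.groupby("group") if len(sub) >= min_clade_size
    ]

    for gname, resid in groups:
        taxa = list(resid.index)
        sub_tree = tree if gname == "all" else prune_tree(tree, taxa)
        C = bm_vcv(sub_tree, taxa=taxa)
        A = abouheif_proximity(sub_tree).reorder(taxa)
        models: dict[str, dict] = {}
        if pairwise_D is not None:
            Dp = pairwise_D.reorder(taxa)
            models["pairwise"] = {
                "W": distance_to_weights(Dp, weight_scheme),
                "D": Dp,
            }
        models["abouheif"] = {
            "W": proximity_to_weights(A),
            "D": proximity_to_dissimilarity(A),
        }
        for col in trait_columns:
            z = resid[f"{col}_res"].to_numpy()
            for mname, mats in models.items():
                if "moran" in tests:
                    r = morans_i_mc(z, mats["W"], n_perm, next_seed(),
                                    distance_model=mname, group=gname)
                    rows.append(_result_row(r, col))
                if "geary" in tests:
                    r = gearys_c_mc(z, mats["W"], n_perm, next_seed(),
                                    distance_model=mname, group=gname)
                    rows.append(_result_row(r, col))
            if "blomberg_k" in tests:
                r = blombergs_k_mc(z, C, n_perm, next_seed(),
                                   distance_model="bm_vcv", group=gname)
                rows.append(_result_row(r, col))

        if "mantel" in tests:
            if gname == "all" and run_stepwise:
                trace_dict = {}
                for mname, mats in models.items():
                    est = ForwardStepwiseMantel(
                        n_boot=n_boot, n_perm=n_perm, seed=next_seed()
                    ).fit(resid, mats["D"])
                    selected[mname] = est.selected_traits_
                    trace_dict[mname] = est.trace_.to_dict()
                    fr = est.final_result_
                    fr.distance_model = mname
                    fr.group = gname
                    rows.append(_result_row(fr, "+".join(est.selected_traits_)))
            else:
                for mname, mats in models.items():
                    traits_sel = selected.get(mname) or list(trait_columns)
                    DT = euclidean_trait_distance(resid, traits_sel)
                    r = mantel_mc(DT, mats["D"], n_perm, next_seed(),
                                  distance_model=mname, group=gname)
                    rows.append(_result_row(r, "+".join(traits_sel)))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if holm:  # off by default: the table convention is per-test stars
        from statsmodels.stats.multitest import multipletests

        results["p_holm"] = multipletests(results["p_mc"], method="holm")[1]
    residuals = pd.concat([res_all, res_clade])
    return results, trace_dict, residuals


# --------------------------------------------------------------- full pipeline

@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    metadata: str
    tree: str
    alignment: str | None = None
    distances: str | None = None  # pre-computed distance TSV escape hatch
    audio_root: str = "."
    out_dir: str = "results"
    distance_model: str = "jc69"
    weight_scheme: str = "inverse"
    n_perm: int = 10_000
    n_boot: int = 10_000
    seed: int = 0
    min_clade_size: int = 5
    prune_to_intersection: bool = False
    holm: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_recordings(meta: pd.DataFrame, audio_root: str | Path) -> list:
    recs = []
    root = Path(audio_root)
    for _, row in meta.iterrows():
        paths = str(row.get("wav_paths", "")).split(";")
        for k, rel in enumerate(p for p in paths if p.strip()):
            recs.append(
                read_wav(root / rel.strip(), species_id=row["species_id"],
                         recording_id=f"{row['species_id']}_r{k + 1}")
            )
    return recs


def run_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline and write all artifacts to ``cfg.out_dir``.

    Emits: trait table, residual table, results TSV (tests x models x groups),
    stepwise trace JSON and a provenance file (config hash, seed, version).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(cfg.metadata)
    tree = read_tree(cfg.tree)
    recs = load_recordings(meta, cfg.audio_root)
    traits = species_trait_table(recs, meta)

    if cfg.distances:
        D = SquareTaxonMatrix.from_tsv(cfg.distances)
    elif cfg.alignment:
        D = pairwise_distance(read_fasta(cfg.alignment), cfg.distance_model)
    else:
        D = None

    rep = validate_inputs(traits.index, tree, None if D is None else D.taxa)
    if not rep.ok:
        raise ValueError(f"species-id mismatch: {rep}")
    if rep.prunable and not cfg.prune_to_intersection:
        raise ValueError(
            f"extra taxa present (pass prune_to_intersection): {rep}"
        )

    results, trace, residuals = run_table(
        traits,
        tree,
        D,
        n_perm=cfg.n_perm,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        min_clade_size=cfg.min_clade_size,
        weight_scheme=cfg.weight_scheme,
        holm=cfg.holm,
    )
    traits.to_csv(out / "trait_table.tsv", sep="\t", float_format="%.8g")
    residuals.to_csv(out / "residuals.tsv", sep="\t", float_format="%.8g")
    results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6g")
    if trace is not None:
        (out / "stepwise_trace.json").write_text(json.dumps(trace, indent=1))
    provenance = {
        "version": __version__,
        "config": cfg.__dict__,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return {"results": results, "trace": trace, "traits": traits, "residuals": residuals}
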