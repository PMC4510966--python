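"""Config-driven orchestration of the full comparative analysis.

Stages, in order: load and validate inputs; intrinsic hand proportions
with ANOVA; extrinsic hand proportions; species means; covariance-PCA
(individual-level and species-mean, optionally ray-IV only); surface
regime search on the leading species-mean PC axes; AICc comparison of
the configured hypothesis set (BM, single-regime OU, user clade-OU
models and the surface-derived painting); ancestral states /
phylomorphospace with LCA confidence intervals; Blomberg's K per axis.
Every stage writes CSV/JSON artefacts and the run closes with a
manifest recording seeds, the config hash and every output, so any
stage can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import morphometrics as mm
from .ancestral import build_phylomorphospace
from .evo_models import compare_models, multivariate_fit
from .phylo_signal import k_permutation_test
from .regime_search import DEFAULT_MIN_IMPROVEMENT, surface_search
from .tree import PhyloTree, paint_clades, read_newick, uniform_painting

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    specimen_csv: str
    tree_newick: str
    out_dir: str
    hypotheses_json: str | None = None
    seed: int = 0
    n_pc_axes: int = 2
    run_ihp: bool = True
    run_ehp: bool = True
    run_ray4: bool = False
    run_surface: bool = True
    run_hypotheses: bool = True
    run_ancestral: bool = True
    run_signal: bool = True
    body_mass_mode: str = "measured"  # measured | fhd_regression | fixed
    fixed_masses: dict | None = None
    dual_mass_taxon: str | None = None  # sensitivity pair for one taxon
    dual_mass_values: tuple | None = None
    drop_taxa: tuple = ()  # leave-taxa-out rerun (fossil sensitivity)
    lca_pair: tuple = ("Pan_troglodytes", "Homo_sapiens")
    min_improvement: float | None = DEFAULT_MIN_IMPROVEMENT
    k_permutations: int = 1000

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.dual_mass_values is not None:
            cfg.dual_mass_values = tuple(cfg.dual_mass_values)
        cfg.drop_taxa = tuple(cfg.drop_taxa)
        cfg.lca_pair = tuple(cfg.lca_pair)
        return cfg

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return json.dumps(d, indent=2, sort_keys=True)


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(cfg.to_json().encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, manifest, stage, **kw) -> None:
    df.to_csv(path, float_format="%.12g", **kw)
    manifest["outputs"].append({"stage": stage, "path": path.name})


def _write_json(obj, path: Path, manifest, stage) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
    manifest["outputs"].append({"stage": stage, "path": path.name})


def _resolve_masses(records, cfg: PipelineConfig):
    """Fill in missing body masses according to the configured mode."""
    if cfg.body_mass_mode == "measured":
        return records
    if cfg.body_mass_mode == "fixed":
        fixed = cfg.fixed_masses or {}
        out = []
        for r in records:
            if r.taxon in fixed:
                r = mm.SpecimenRecord(
                    **{**r.__dict__, "bm_kg": float(fixed[r.taxon]),
                       "mass_estimated": True}
                )
            out.append(r)
        return out
    if cfg.body_mass_mode != "fhd_regression":
        raise PipelineError(f"body_mass: unknown mode {cfg.body_mass_mode!r}")
    # group-specific (taxon-level) regressions from specimens with both
    # recorded BM and FHD, applied to the rest of the same taxon
    out = []
    by_taxon: dict[str, list] = {}
    for r in records:
        by_taxon.setdefault(r.taxon, []).append(r)
    for taxon, recs in by_taxon.items():
        pairs = [(r.fhd_mm, r.bm_kg) for r in recs
                 if r.fhd_mm is not None and r.bm_kg is not None]
        reg = mm.fit_mass_regression(pairs) if len(pairs) >= 3 else None
        for r in recs:
            if r.bm_kg is None and reg is not None and r.fhd_mm is not None:
                r = mm.estimate_body_mass(r, reg)
            out.append(r)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every enabled stage; returns the manifest dict."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "outputs": [],
        "stages": [],
        "dropped_taxa": list(cfg.drop_taxa),
    }
    (out / "config.json").write_text(cfg.to_json())

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        if not Path(cfg.specimen_csv).exists():
            raise PipelineError(f"load: specimen CSV {cfg.specimen_csv} not found")
        if not Path(cfg.tree_newick).exists():
            raise PipelineError(f"load: tree file {cfg.tree_newick} not found")
        records = mm.read_specimen_csv(cfg.specimen_csv)
        tree = read_newick(Path(cfg.tree_newick).read_text())
        records = [r for r in records if r.taxon not in cfg.drop_taxa]
        if cfg.drop_taxa:
            tree = _prune(tree, cfg.drop_taxa)
        records = _resolve_masses(records, cfg)

        mass_iterations = [("run", None)]
        if cfg.dual_mass_taxon and cfg.dual_mass_values:
            mass_iterations = [
                (f"mass_{v:g}kg", (cfg.dual_mass_taxon, float(v)))
                for v in cfg.dual_mass_values
            ]

        for tag, override in mass_iterations:
            recs = records
            if override is not None:
                taxon, value = override
                recs = [
                    mm.SpecimenRecord(**{**r.__dict__, "bm_kg": value,
                                         "mass_estimated": True})
                    if r.taxon == taxon else r
                    for r in records
                ]
            _run_once(cfg, tree, recs, out, tag, manifest)

        manifest["runtime_s"] = round(time.time() - t0, 3)
        _write_json(manifest, out / "manifest.json", manifest, "manifest")
    except PipelineError:
        (out / "FAILED").write_text("see log")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}")
        raise PipelineError(f"{manifest['stages'][-1]}: {exc}") from exc
    return manifest


def _prune(tree: PhyloTree, drop) -> PhyloTree:
    """Drop tips by label, suppressing the resulting unifurcations."""
    keep = [l for l in tree.tip_labels if l not in set(drop)]
    if len(keep) < 3:
        raise PipelineError("prune: fewer than 3 tips would remain")
    import dendropy

    d = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                          preserve_underscores=True)
    d.retain_taxa_with_labels(keep)
    d.suppress_unifurcations()
    return read_newick(d.as_string(schema="newick").strip())


def _run_once(cfg, tree, records, out: Path, tag: str, manifest) -> None:
    prefix = "" if tag == "run" else f"{tag}_"

    if cfg.run_ihp:
        _stage_ihp(records, out, prefix, manifest)

    species_scores = None
    if cfg.run_ehp:
        species_scores = _stage_ehp(cfg, tree, records, out, prefix, manifest)
    if cfg.run_ray4:
        _stage_variant(cfg, tree, records, out, prefix, manifest, "ray4")

    if species_scores is None:
        return
    X = species_scores.iloc[:, : cfg.n_pc_axes]

    painting = None
    if cfg.run_surface:
        manifest["stages"].append(f"{prefix}surface")
        painting, trace, fit = surface_search(
            tree, X, min_improvement=cfg.min_improvement
        )
        (out / f"{prefix}surface_trace.jsonl").write_text(trace.to_jsonl())
        manifest["outputs"].append(
            {"stage": f"{prefix}surface", "path": f"{prefix}surface_trace.jsonl"}
        )
        pd.DataFrame(
            painting.as_table(), columns=["child_id", "parent_id", "regime"]
        ).pipe(_write_csv, out / f"{prefix}surface_painting.csv", manifest,
               f"{prefix}surface", index=False)
        _write_json(fit.to_dict(), out / f"{prefix}surface_fit.json", manifest,
                    f"{prefix}surface")

    if cfg.run_hypotheses:
        manifest["stages"].append(f"{prefix}hypotheses")
        fits = [
            multivariate_fit(tree, None, X, model="bm", name="BM"),
            multivariate_fit(tree, uniform_painting(tree), X, name="OU1"),
        ]
        if cfg.hypotheses_json:
            for hyp in json.loads(Path(cfg.hypotheses_json).read_text()):
                specs = [(c["label"], c["tips"]) for c in hyp["clades"]]
                paint = paint_clades(tree, specs)
                fits.append(multivariate_fit(tree, paint, X, name=hyp["name"]))
        if painting is not None:
            fits.append(multivariate_fit(tree, painting, X, name="surface"))
        compare_models(fits)
        _write_json([f.to_dict() for f in fits],
                    out / f"{prefix}model_comparison.json", manifest,
                    f"{prefix}hypotheses")

    if cfg.run_ancestral:
        manifest["stages"].append(f"{prefix}phylomorphospace")
        pms = build_phylomorphospace(tree, X)
        _write_csv(pms.nodes, out / f"{prefix}phylomorphospace_nodes.csv",
                   manifest, f"{prefix}phylomorphospace", index=False)
        _write_csv(pms.edges, out / f"{prefix}phylomorphospace_edges.csv",
                   manifest, f"{prefix}phylomorphospace", index=False)
        a, b = cfg.lca_pair
        if a in tree.tip_labels and b in tree.tip_labels:
            _write_json(pms.lca(a, b).to_dict(),
                        out / f"{prefix}lca_{a}_{b}.json", manifest,
                        f"{prefix}phylomorphospace")

    if cfg.run_signal:
        manifest["stages"].append(f"{prefix}signal")
        rows = []
        for j, axis in enumerate(X.columns):
            ks = k_permutation_test(
                tree, X[axis], n_perm=cfg.k_permutations, seed=cfg.seed + j
            )
            rows.append({"trait": axis, "K": ks.k,
                         "expected_ratio": ks.expected_ratio, "p": ks.p_value,
                         "n_perm": ks.n_perm, "tail": ks.tail,
                         "scores": "species-mean PCA"})
        _write_csv(pd.DataFrame(rows), out / f"{prefix}blomberg_k.csv",
                   manifest, f"{prefix}signal", index=False)


def _stage_ihp(records, out, prefix, manifest) -> None:
    manifest["stages"].append(f"{prefix}ihp")
    rows, groups, values = [], [], []
    for r in records:
        try:
            v = mm.compute_ihp(r)
        except mm.MissingElementError:
            continue
        rows.append({"taxon": r.taxon, "specimen_id": r.specimen_id, "ihp": v})
        groups.append(r.taxon)
        values.append(v)
    df = pd.DataFrame(rows)
    if df.empty:
        raise PipelineError("ihp: no specimen has all six elements")
    _write_csv(df, out / f"{prefix}ihp_specimens.csv", manifest,
               f"{prefix}ihp", index=False)
    counts = df.groupby("taxon").size()
    usable = counts[counts >= 2].index
    mask = df["taxon"].isin(usable)
    if usable.size >= 2:
        cmp_ = mm.group_compare(df.loc[mask, "ihp"], df.loc[mask, "taxon"])
        _write_csv(cmp_.pairwise, out / f"{prefix}ihp_anova_pairwise.csv",
                   manifest, f"{prefix}ihp", index=False)
        _write_json({"F": cmp_.f_statistic, "p": cmp_.p_value},
                    out / f"{prefix}ihp_anova.json", manifest, f"{prefix}ihp")


def _stage_ehp(cfg, tree, records, out, prefix, manifest):
    manifest["stages"].append(f"{prefix}ehp")
    rows = []
    for r in records:
        try:
            ratios = mm.compute_ehp(r)
        except mm.MissingElementError:
            continue
        rows.append({"taxon": r.taxon, "specimen_id": r.specimen_id, **ratios})
    ind = pd.DataFrame(rows)
    if ind.empty:
        raise PipelineError("ehp: no specimen has six elements plus body mass")
    _write_csv(ind, out / f"{prefix}ehp_specimens.csv", manifest,
               f"{prefix}ehp", index=False)

    pca_ind = mm.pca_covariance(ind[list(mm.ELEMENTS)])
    _write_csv(pca_ind.scores.assign(taxon=ind["taxon"].values),
               out / f"{prefix}pca_individual_scores.csv", manifest,
               f"{prefix}ehp", index=False)

    means = mm.species_means(records, "ehp")
    missing = [t for t in tree.tip_labels if t not in means.index]
    if missing:
        raise PipelineError(f"ehp: tree tips without specimen data: {missing}")
    means = means.loc[tree.tip_labels]
    _write_csv(means, out / f"{prefix}species_means.csv", manifest, f"{prefix}ehp")
    pca_sp = mm.pca_covariance(means)
    _write_csv(pca_sp.scores, out / f"{prefix}pca_species_scores.csv",
               manifest, f"{prefix}ehp")
    _write_csv(pca_sp.loadings(), out / f"{prefix}pca_species_loadings.csv",
               manifest, f"{prefix}ehp")
    _write_json(
        {"proportion": pca_sp.proportion.tolist(),
         "eigenvalues": pca_sp.eigenvalues.tolist(),
         "pc12_variance": float(pca_sp.proportion[:2].sum())},
        out / f"{prefix}pca_species_summary.json", manifest, f"{prefix}ehp",
    )
    return pca_sp.scores


def _stage_variant(cfg, tree, records, out, prefix, manifest, which) -> None:
    """Ray-IV-only PCA variant (for thumbless fossil material)."""
    manifest["stages"].append(f"{prefix}{which}")
    try:
        means = mm.species_means(records, which)
    except ValueError as exc:
        raise PipelineError(f"{which}: {exc}") from exc
    keep = [t for t in tree.tip_labels if t in means.index]
    means = means.loc[keep]
    pca = mm.pca_covariance(means)
    _write_csv(pca.scores, out / f"{prefix}pca_{which}_scores.csv",
               manifest, f"{prefix}{which}")
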