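"""Synthetic trees and specimen data with the study's statistical structure.

The real measurements behind the hand-proportion analyses live in
museum records; these generators produce data with the same shape so
the whole pipeline can be exercised and validated end to end:

* a packaged anthropoid tree (15 extant terminals: hominoids to
  species, monkeys to genus, hylobatids pooled) with graft points for
  four fossils (Ardipithecus ramidus 4.4 Myr, Australopithecus sediba
  ~2 Myr, Proconsul heseloni ~18 Myr, Hispanopithecus laietanus
  9.6 Myr) attached through 1-Myr ghost lineages;
* taxon-mean log shape ratios evolving under a painted multi-regime OU
  process (exact transition sampling along each branch);
* specimen-level multiplicative (lognormal) scatter around the taxon
  means, and body mass linked to bone lengths through cube-root
  scaling, so that recomputing EHP ratios from the specimen table
  recovers the simulated means.

Extant node ages in the packaged tree are rounded literature-standard
dates; fossil tip ages follow the published first-appearance dates.
They are fixture constants, not scientific claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometrics import ELEMENTS
from .tree import (
    PhyloTree,
    RegimePainting,
    graft_fossil,
    make_hispanopithecus_trees,
    read_newick,
    uniform_painting,
)

__all__ = [
    "SimulationSpec",
    "sim_tree",
    "packaged_anthropoid_tree",
    "simulate_bm",
    "simulate_ou",
    "simulate_study",
    "FIG1_SPECIMEN_COUNTS",
    "DEFAULT_TAXON_MASS_KG",
]

# Per-taxon sample sizes of the intrinsic-proportion dataset (the
# study's boxplot caption); fossils get their associated-specimen counts.
FIG1_SPECIMEN_COUNTS = {
    "Homo_sapiens": 40,
    "Pan_troglodytes": 34,
    "Pan_paniscus": 12,
    "Gorilla_beringei": 21,
    "Gorilla_gorilla": 13,
    "Pongo_abelii": 8,
    "Pongo_pygmaeus": 19,
    "Hylobatidae": 14,
    "Theropithecus": 5,
    "Papio": 50,
    "Mandrillus": 3,
    "Macaca": 18,
    "Nasalis": 14,
    "Cebus": 11,
    "Alouatta": 8,
    "Ardipithecus_ramidus": 1,
    "Australopithecus_sediba": 1,
    "Proconsul_heseloni": 3,
    "Hispanopithecus_laietanus": 1,
}

# Round literature body masses (kg) used as taxon means by the generator.
DEFAULT_TAXON_MASS_KG = {
    "Homo_sapiens": 60.0,
    "Pan_troglodytes": 45.0,
    "Pan_paniscus": 35.0,
    "Gorilla_beringei": 120.0,
    "Gorilla_gorilla": 100.0,
    "Pongo_abelii": 45.0,
    "Pongo_pygmaeus": 50.0,
    "Hylobatidae": 6.0,
    "Theropithecus": 15.0,
    "Papio": 20.0,
    "Mandrillus": 25.0,
    "Macaca": 8.0,
    "Nasalis": 15.0,
    "Cebus": 3.0,
    "Alouatta": 6.0,
    "Ardipithecus_ramidus": 50.8,
    "Australopithecus_sediba": 32.5,
    "Proconsul_heseloni": 10.0,
    "Hispanopithecus_laietanus": 37.25,
}

# Extant backbone: node ages (Myr) are rounded literature dates.
_EXTANT_NEWICK = (
    "((Alouatta:20,Cebus:20):20,"
    "((Nasalis:18,(Macaca:12,(Mandrillus:9,(Papio:5,Theropithecus:5):4):3):6):12,"
    "(Hylobatidae:18.5,((Pongo_abelii:1,Pongo_pygmaeus:1):15,"
    "((Gorilla_beringei:1.2,Gorilla_gorilla:1.2):7.8,"
    "((Pan_troglodytes:2.5,Pan_paniscus:2.5):4.5,Homo_sapiens:7):2):7):2.5):11.5):10);"
)

FOSSIL_AGES = {
    "Ardipithecus_ramidus": 4.4,
    "Australopithecus_sediba": 1.98,
    "Proconsul_heseloni": 18.0,
    "Hispanopithecus_laietanus": 9.6,
}

# Baseline log shape ratios (log mm/kg^(1/3)); roughly 30 mm elements
# on a 10-kg frame.  Thumb elements shorter than ray-IV elements.
_BASE_LOG_RATIO = {
    "mc1": np.log(18.0),
    "pp1": np.log(13.0),
    "dp1": np.log(8.0),
    "mc4": np.log(28.0),
    "pp4": np.log(18.0),
    "ip4": np.log(11.0),
}


def sim_tree(n_tips: int, total_height: float, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree rescaled to a fixed height; ultrametric."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    # grow: start from the root split, split a random lineage at each event
    parent = [-1, 0, 0]
    blen = [np.nan, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    events = [0.0]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        events.append(t)
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        a, b = len(parent), len(parent) + 1
        parent.extend([node, node])
        blen.extend([0.0, 0.0])
        active.extend([a, b])
        # fix the split node's depth by recording its birth time
        blen[node] = t  # temporarily store absolute split time on the node
    t_end = t + rng.exponential(1.0 / len(active))
    # convert stored absolute times into branch lengths
    depth = [0.0] * len(parent)
    split_time = {0: 0.0}
    for i in range(1, len(parent)):
        split_time[i] = blen[i] if i not in active else t_end
    lengths = [np.nan] * len(parent)
    for i in range(1, len(parent)):
        lengths[i] = split_time[i] - split_time[parent[i]]
        if lengths[i] <= 0:
            lengths[i] = 1e-9  # simultaneous events cannot happen a.s.
    scale = total_height / t_end
    lengths = [l * scale if np.isfinite(l) else np.nan for l in lengths]
    labels = {i: f"t{k + 1}" for k, i in enumerate(active)}
    return PhyloTree(parent, lengths, labels)


def packaged_anthropoid_tree(
    fossils: bool = True, hispanopithecus: str | None = None
) -> PhyloTree:
    """The packaged anthropoid topology, optionally with fossils grafted.

    ``hispanopithecus`` selects the placement variant ("stem_great_ape",
    "stem_pongine" or "stem_hominine"); ``None`` omits that taxon.
    """
    tree = read_newick(_EXTANT_NEWICK)
    if not fossils:
        return tree
    tree = graft_fossil(
        tree, "Proconsul_heseloni", FOSSIL_AGES["Proconsul_heseloni"],
        ("Hylobatidae", "Homo_sapiens"),
    )
    tree = graft_fossil(
        tree, "Ardipithecus_ramidus", FOSSIL_AGES["Ardipithecus_ramidus"],
        "Homo_sapiens",
    )
    tree = graft_fossil(
        tree, "Australopithecus_sediba", FOSSIL_AGES["Australopithecus_sediba"],
        "Homo_sapiens",
    )
    if hispanopithecus is not None:
        variants = make_hispanopithecus_trees(tree)
        if hispanopithecus not in variants:
            raise KeyError(
                f"unknown placement {hispanopithecus!r}; "
                f"choose from {sorted(variants)}"
            )
        tree = variants[hispanopithecus]
    return tree


def _simulate_states(tree, painting, alpha, sigma2, theta, rng):
    """Exact OU (or BM when alpha is None) transition sampling, all nodes."""
    states = {}
    for node in tree.preorder():
        if node == tree.root:
            states[node] = theta[painting.root_label] if alpha is not None else theta
            continue
        parent = states[int(tree.parent[node])]
        t = float(tree.blen[node])
        if alpha is None:  # Brownian motion
            states[node] = parent + rng.normal(0.0, np.sqrt(sigma2 * t))
        else:
            th = theta[painting.branch_regime[node]]
            decay = np.exp(-alpha * t)
            var = sigma2 / (2.0 * alpha) * (-np.expm1(-2.0 * alpha * t))
            states[node] = th + (parent - th) * decay + (
                rng.normal(0.0, np.sqrt(var)) if var > 0 else 0.0
            )
    return states


def simulate_bm(tree: PhyloTree, sigma2: float, root_state: float, seed) -> pd.Series:
    """Tip values from recursive BM: child = parent + N(0, sigma2 * t)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = _simulate_states(tree, None, None, sigma2, root_state, rng)
    return pd.Series({tree.labels[t]: states[t] for t in tree.tips}, name="bm")


def simulate_ou(
    tree: PhyloTree,
    painting: RegimePainting,
    alpha: float,
    sigma2: float,
    theta: dict,
    seed,
) -> pd.Series:
    """Tip values from exact per-branch OU transitions.

    The root starts at the root regime's optimum; along each branch
    child = theta + (parent - theta) e^(-alpha t) + N(0, v(t)) with
    v(t) = sigma^2 (1 - e^(-2 alpha t)) / (2 alpha).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = _simulate_states(tree, painting, alpha, sigma2, theta, rng)
    return pd.Series({tree.labels[t]: states[t] for t in tree.tips}, name="ou")


@dataclass
class SimulationSpec:
    """Conditions for a full synthetic specimen study.

    ``theta_shift`` gives per-regime additive shifts (log-ratio units)
    applied on top of the baseline element means; ``clades`` maps
    regime labels to tip-label lists (shared labels = planted
    convergence).  Defaults plant the Pan+Pongo convergent
    digital-elongation regime and a distinct human/hominin regime.
    """

    seed: int
    tree: PhyloTree | None = None
    clades: dict = field(
        default_factory=lambda: {
            "suspensory": [
                ["Pan_troglodytes", "Pan_paniscus"],
                ["Pongo_abelii", "Pongo_pygmaeus"],
            ],
            "hominin": [["Homo_sapiens"]],
        }
    )
    # per-regime shifts on log shape ratios; digits lengthen under the
    # suspensory regime while the thumb shortens, and vice versa for
    # the hominin regime.  Magnitudes are many stationary SDs: the
    # planted structure emulates a decisively supported signal.
    theta_shift: dict = field(
        default_factory=lambda: {
            "suspensory": {"mc1": -0.2, "pp1": -0.25, "dp1": -0.25,
                           "mc4": 0.55, "pp4": 0.65, "ip4": 0.65},
            "hominin": {"mc1": 0.35, "pp1": 0.4, "dp1": 0.4,
                        "mc4": -0.35, "pp4": -0.4, "ip4": -0.4},
        }
    )
    alpha: float = 0.5  # 1/Myr: phenotypic half-life ~1.4 Myr (strong pull)
    sigma2: float = 0.0004  # log-ratio^2 / Myr: stationary SD 0.02
    shape_cv: float = 0.05  # within-taxon specimen scatter of log ratios
    mass_cv: float = 0.15  # within-taxon lognormal body-mass scatter
    specimen_counts: dict = field(default_factory=dict)
    taxon_mass: dict = field(default_factory=dict)
    missing_rate: float = 0.0  # uniform missing-at-random element mask
    fhd_slope: float = 2.5  # log10 BM on log10 FHD used to emit FHD values
    fhd_intercept: float = -2.0

    def __post_init__(self):
        if self.alpha <= 0 or self.sigma2 <= 0:
            raise ValueError("rates must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        counts = dict(FIG1_SPECIMEN_COUNTS)
        counts.update(self.specimen_counts)
        self.specimen_counts = counts
        mass = dict(DEFAULT_TAXON_MASS_KG)
        mass.update(self.taxon_mass)
        self.taxon_mass = mass


def simulate_study(spec: SimulationSpec):
    """Generate (tree, specimen table, truth record) for a full study.

    Taxon-mean log shape ratios of the six elements evolve under the
    painted OU model; each specimen then gets a lognormal body mass
    around its taxon mean and element lengths
    exp(taxon log ratio + N(0, shape_cv)) * BM^(1/3), so that EHP
    ratios computed from the table scatter around the simulated means.
    FHD values consistent with the spec's allometric law are emitted
    for every specimen.
    """
    tree = spec.tree if spec.tree is not None else packaged_anthropoid_tree()
    from .tree import paint_clades

    clade_specs = []
    for label, groups in spec.clades.items():
        for tips in groups:
            missing = [t for t in tips if t not in tree.tip_labels]
            if missing:
                raise ValueError(f"regime {label!r} references unknown tips {missing}")
            clade_specs.append((label, tips))
    painting = (
        paint_clades(tree, clade_specs) if clade_specs else uniform_painting(tree)
    )
    used = set(painting.branch_regime.values())
    for label in spec.clades:
        if label not in used:
            raise ValueError(f"regime {label!r} paints no branch")
    rng = np.random.default_rng(spec.seed)
    truth_means: dict[str, dict[str, float]] = {}
    tip_logratio: dict[str, dict[str, float]] = {}
    for element in ELEMENTS:
        theta = {painting.root_label: _BASE_LOG_RATIO[element]}
        for label in spec.clades:
            theta[label] = _BASE_LOG_RATIO[element] + spec.theta_shift.get(
                label, {}
            ).get(element, 0.0)
        col = simulate_ou(tree, painting, spec.alpha, spec.sigma2, theta, rng)
        truth_means[element] = {k: float(v) for k, v in col.items()}
        for taxon, v in col.items():
            tip_logratio.setdefault(taxon, {})[element] = float(v)

    rows = []
    for taxon in tree.tip_labels:
        n = int(spec.specimen_counts.get(taxon, 10))
        mass_mean = float(spec.taxon_mass.get(taxon, 10.0))
        for k in range(n):
            bm = mass_mean * np.exp(rng.normal(0.0, spec.mass_cv))
            row = {"taxon": taxon, "specimen_id": f"{taxon}_{k + 1:03d}"}
            size = bm ** (1.0 / 3.0)
            for element in ELEMENTS:
                lr = tip_logratio[taxon][element] + rng.normal(0.0, spec.shape_cv)
                row[element] = float(np.exp(lr) * size)
            # FHD consistent with the allometric law, with mild scatter
            log10_fhd = (np.log10(bm) - spec.fhd_intercept) / spec.fhd_slope
            row["fhd_mm"] = float(10.0 ** (log10_fhd + rng.normal(0.0, 0.01)))
            row["bm_kg"] = float(bm)
            rows.append(row)
    specimens = pd.DataFrame(rows)
    if spec.missing_rate > 0.0:
        mask = rng.random((len(specimens), len(ELEMENTS))) < spec.missing_rate
        for j, element in enumerate(ELEMENTS):
            specimens.loc[mask[:, j], element] = np.nan
    truth = {
        "seed": spec.seed,
        "painting": painting.to_dict(),
        "alpha": spec.alpha,
        "sigma2": spec.sigma2,
        "shape_cv": spec.shape_cv,
        "mass_cv": spec.mass_cv,
        "taxon_log_ratio_means": truth_means,
        "taxon_mass": {t: spec.taxon_mass.get(t) for t in tree.tip_labels},
    }
    return tree, specimens, truth
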