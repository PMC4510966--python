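"""Hand-proportion morphometrics, body-mass allometry, PCA and group tests.

Intrinsic hand proportions (IHP) measure thumb length against the
fourth ray:

    IHP = (MC1 + PP1 + DP1) / (MC4 + PP4 + IP4)

with the fourth-ray distal phalanx excluded (it is poorly represented
in skeletal and fossil material).  Extrinsic hand proportions (EHP)
standardize each of the six element lengths by the cube root of body
mass — mass being proportional to volume, its cube root is the nominal
linear size — yielding shape ratios in mm / kg^(1/3).

Ratios are computed per specimen and then averaged per taxon (mean of
ratios, never ratio of means).  Body mass, when unrecorded, is
predicted from femoral head diameter through group-specific log10–log10
least-squares regressions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

ELEMENTS = ("mc1", "pp1", "dp1", "mc4", "pp4", "ip4")
THUMB = ("mc1", "pp1", "dp1")
RAY4 = ("mc4", "pp4", "ip4")

__all__ = [
    "ELEMENTS",
    "SpecimenRecord",
    "MassRegression",
    "PCAResult",
    "MissingElementError",
    "read_specimen_csv",
    "compute_ihp",
    "compute_ehp",
    "fit_mass_regression",
    "estimate_body_mass",
    "species_means",
    "pca_covariance",
    "group_compare",
]


class MissingElementError(ValueError):
    """A required measurement is absent from a specimen record."""


@dataclass
class SpecimenRecord:
    """One museum specimen: six hand-bone lengths plus size data.

    Lengths in mm: thumb metacarpal (mc1), proximal (pp1) and distal
    (dp1) phalanges; fourth-ray metacarpal (mc4), proximal (pp4) and
    intermediate (ip4) phalanges.  ``bm_kg`` is body mass; ``fhd_mm``
    femoral head diameter.  ``None`` marks a missing measurement.
    """

    taxon: str
    specimen_id: str
    mc1: float | None = None
    pp1: float | None = None
    dp1: float | None = None
    mc4: float | None = None
    pp4: float | None = None
    ip4: float | None = None
    bm_kg: float | None = None
    fhd_mm: float | None = None
    mass_estimated: bool = False

    def __post_init__(self):
        for name in (*ELEMENTS, "bm_kg", "fhd_mm"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(
                    f"{self.specimen_id}: {name} must be positive, got {v}"
                )

    def require(self, names) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise MissingElementError(
                f"{self.taxon} {self.specimen_id}: missing {', '.join(missing)}"
            )


def read_specimen_csv(path) -> list[SpecimenRecord]:
    """Load the specimen table (empty cells = missing measurements)."""
    df = pd.read_csv(path)
    needed = {"taxon", "specimen_id"}
    if not needed <= set(df.columns):
        raise ValueError(f"specimen CSV must have columns {sorted(needed)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for name in (*ELEMENTS, "bm_kg", "fhd_mm"):
            v = row.get(name)
            kwargs[name] = None if v is None or pd.isna(v) else float(v)
        records.append(
            SpecimenRecord(str(row["taxon"]), str(row["specimen_id"]), **kwargs)
        )
    return records


def compute_ihp(rec: SpecimenRecord) -> float:
    """Thumb / fourth-ray length ratio (dimensionless)."""
    rec.require(ELEMENTS)
    thumb = sum(getattr(rec, n) for n in THUMB)
    ray = sum(getattr(rec, n) for n in RAY4)
    return thumb / ray


def compute_ehp(rec: SpecimenRecord) -> dict[str, float]:
    """Six mass-standardized shape ratios, mm / kg^(1/3)."""
    rec.require(ELEMENTS)
    if rec.bm_kg is None:
        raise MissingElementError(
            f"{rec.taxon} {rec.specimen_id}: no body mass (measured or estimated) "
            "to standardize by"
        )
    size = rec.bm_kg ** (1.0 / 3.0)
    return {n: getattr(rec, n) / size for n in ELEMENTS}


@dataclass
class MassRegression:
    """log10(BM) = intercept + slope * log10(FHD), least squares."""

    slope: float
    intercept: float
    r2: float
    see: float  # standard error of the estimate (log10 units)
    n: int

    def predict(self, fhd_mm: float) -> float:
        return 10.0 ** (self.intercept + self.slope * math.log10(fhd_mm))


def fit_mass_regression(pairs) -> MassRegression:
    """Fit body mass on femoral head diameter in log10–log10 space."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 (FHD, BM) pairs, got {len(pairs)}")
    fhd = np.array([p[0] for p in pairs], dtype=float)
    bm = np.array([p[1] for p in pairs], dtype=float)
    if np.any(fhd <= 0) or np.any(bm <= 0):
        raise ValueError("FHD and BM must all be positive")
    lx, ly = np.log10(fhd), np.log10(bm)
    res = stats.linregress(lx, ly)
    resid = ly - (res.intercept + res.slope * lx)
    dof = max(len(pairs) - 2, 1)
    return MassRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        see=float(np.sqrt(resid @ resid / dof)),
        n=len(pairs),
    )


def estimate_body_mass(rec: SpecimenRecord, reg: MassRegression | list) -> SpecimenRecord:
    """Predict body mass from FHD; flags the record's mass as estimated.

    ``reg`` may be a list of regressions (e.g. quadrupedal and bipedal
    reference samples), in which case the predictions are averaged —
    the convention used for fossils whose locomotor reference sample is
    ambiguous.
    """
    if rec.fhd_mm is None:
        raise MissingElementError(
            f"{rec.taxon} {rec.specimen_id}: no FHD to estimate body mass from"
        )
    regs = reg if isinstance(reg, (list, tuple)) else [reg]
    bm = float(np.mean([r.predict(rec.fhd_mm) for r in regs]))
    out = SpecimenRecord(**{**rec.__dict__, "bm_kg": bm, "mass_estimated": True})
    return out


def species_means(records, traits="ehp") -> pd.DataFrame:
    """Taxon-mean trait matrix (ratios first, then arithmetic mean).

    ``traits`` selects the ratio set: ``"ehp"`` (six mass-standardized
    ratios), ``"ihp"`` (single thumb/ray-IV ratio) or ``"ray4"`` (the
    three fourth-ray EHP ratios only, for thumbless material).  Taxa
    with no complete record for the requested set are dropped with a
    warning.
    """
    per_taxon: dict[str, list[dict]] = {}
    skipped: dict[str, int] = {}
    for rec in records:
        try:
            if traits == "ihp":
                row = {"ihp": compute_ihp(rec)}
            elif traits == "ehp":
                row = compute_ehp(rec)
            elif traits == "ray4":
                rec.require(RAY4)
                if rec.bm_kg is None:
                    raise MissingElementError(f"{rec.specimen_id}: no body mass")
                size = rec.bm_kg ** (1.0 / 3.0)
                row = {n: getattr(rec, n) / size for n in RAY4}
            else:
                raise ValueError(f"unknown trait set {traits!r}")
        except MissingElementError:
            skipped[rec.taxon] = skipped.get(rec.taxon, 0) + 1
            continue
        per_taxon.setdefault(rec.taxon, []).append(row)
    for taxon, k in skipped.items():
        if taxon not in per_taxon:
            log.warning("taxon %s dropped: no complete record for %s", taxon, traits)
        else:
            log.info("taxon %s: %d incomplete specimen(s) excluded", taxon, k)
    if not per_taxon:
        raise ValueError(f"no taxon has a complete record for trait set {traits!r}")
    rows = {t: pd.DataFrame(v).mean() for t, v in per_taxon.items()}
    return pd.DataFrame(rows).T.sort_index()


@dataclass
class PCAResult:
    mean: np.ndarray
    eigenvalues: np.ndarray  # descending, >= 0
    eigenvectors: np.ndarray  # orthonormal columns
    scores: pd.DataFrame  # observations x PCs
    proportion: np.ndarray
    columns: list = field(default_factory=list)

    def loadings(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.eigenvectors.shape[1])]
        return pd.DataFrame(self.eigenvectors, index=self.columns, columns=cols)


def pca_covariance(data: pd.DataFrame) -> PCAResult:
    """PCA by eigen-decomposition of the sample covariance matrix (n-1).

    Sign convention: within each eigenvector the loading of largest
    magnitude is made positive, so scores are reproducible across
    linear-algebra backends.
    """
    df = pd.DataFrame(data)
    if df.isna().any().any():
        raise ValueError("PCA input must have no missing values")
    X = df.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError(f"PCA needs >=2 observations and >=2 variables, got {X.shape}")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|loading| entry positive
    for k in range(m):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = Xc @ evecs
    total = evals.sum()
    prop = evals / total if total > 0 else np.zeros_like(evals)
    score_df = pd.DataFrame(
        scores, index=df.index, columns=[f"PC{k + 1}" for k in range(m)]
    )
    return PCAResult(mean, evals, evecs, score_df, prop, list(df.columns))


@dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, t, p_raw, p_bonferroni


def group_compare(values, groups) -> GroupComparison:
    """One-way ANOVA plus Bonferroni-corrected pairwise t-tests."""
    s = pd.Series(np.asarray(values, dtype=float), name="value")
    g = pd.Series(list(groups), name="group")
    if len(s) != len(g):
        raise ValueError("values and groups must have equal length")
    by = {k: v.to_numpy() for k, v in s.groupby(g)}
    small = sorted(k for k, v in by.items() if len(v) < 2)
    if len(by) < 2 or small:
        raise ValueError(
            f"need >=2 groups with >=2 observations each; too small: {small}"
        )
    f, p = stats.f_oneway(*by.values())
    npairs = len(by) * (len(by) - 1) // 2
    rows = []
    for a, b in combinations(sorted(by), 2):
        t, praw = stats.ttest_ind(by[a], by[b])
        rows.append(
            {
                "group1": a,
                "group2": b,
                "t": float(t),
                "p_raw": float(praw),
                "p_bonferroni": min(1.0, float(praw) * npairs),
            }
        )
    return GroupComparison(float(f), float(p), pd.DataFrame(rows))
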