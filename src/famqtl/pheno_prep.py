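"""Blood-pressure phenotype preparation.

Antihypertensive treatment masks the blood pressure an individual would
show untreated, so treated SBP/DBP are imputed by the standard additive
correction (+15 / +10 mmHg). Pulse pressure is the difference of the
adjusted values. Traits are then residualized on covariates (sex, age,
age^2, BMI and genotype principal components) by ordinary least squares;
relatedness is deliberately ignored at this stage and handled downstream
through the kinship matrix, so the same residuals feed linkage and
association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "TraitSpec",
    "adjust_medication",
    "residualize",
    "founder_pca",
    "DEFAULT_COVARIATES",
]

#: standard covariate set for SBP/DBP/PP residualization
DEFAULT_COVARIATES = ("sex", "age", "age2", "bmi", "pc1")

#: covariates when BMI itself is the analyzed trait (BMI excluded)
BMI_COVARIATES = ("sex", "age", "age2", "pc1")

SBP_INCREMENT = 15.0
DBP_INCREMENT = 10.0


@dataclass(frozen=True)
class TraitSpec:
    """Analysis settings for one trait."""

    name: str  # SBP | DBP | PP | BMI
    covariates: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    sbp_increment: float = SBP_INCREMENT
    dbp_increment: float = DBP_INCREMENT

    def __post_init__(self):
        if self.name not in ("SBP", "DBP", "PP", "BMI"):
            raise ValueError(f"unknown trait {self.name!r}")
        if self.covariates is None:
            covs = BMI_COVARIATES if self.name == "BMI" else DEFAULT_COVARIATES
            object.__setattr__(self, "covariates", tuple(covs))
        if self.name == "BMI" and "bmi" in self.covariates:
            raise ValueError("BMI cannot be a covariate for itself")


def adjust_medication(
    pheno: pd.DataFrame,
    *,
    sbp_col: str = "sbp",
    dbp_col: str = "dbp",
    med_col: str = "med",
    sbp_increment: float = SBP_INCREMENT,
    dbp_increment: float = DBP_INCREMENT,
    missing_med: str = "untreated",
) -> pd.DataFrame:
    """Impute treated blood pressures and derive pulse pressure.

    Adds ``sbp_adj``, ``dbp_adj`` (treated individuals get +15/+10 mmHg)
    and ``pp`` = sbp_adj - dbp_adj. A missing medication flag is treated
    as untreated with a warning (``missing_med='error'`` to refuse).
    """
    out = pheno.copy()
    for col in (sbp_col, dbp_col):
        if (out[col].dropna() <= 0).any():
            raise ValueError(f"non-positive values in {col!r}")
    med = out[med_col]
    if med.isna().any():
        if missing_med == "error":
            raise ValueError("missing medication flags")
        logger.warning(
            "%d missing medication flags treated as untreated", int(med.isna().sum())
        )
        med = med.fillna(0)
    treated = med.astype(float) > 0
    out["sbp_adj"] = out[sbp_col] + np.where(treated, sbp_increment, 0.0)
    out["dbp_adj"] = out[dbp_col] + np.where(treated, dbp_increment, 0.0)
    out["pp"] = out["sbp_adj"] - out["dbp_adj"]
    return out


def _design(pheno: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Build the covariate design; 'age2' and 'sex' are derived on the fly."""
    cols = {}
    for cov in covariates:
        if cov == "age2":
            cols["age2"] = pheno["age"].astype(float) ** 2
        elif cov == "sex":
            s = pheno["sex"]
            if s.dtype == object:
                cols["sex"] = (s == "male").astype(float)
            else:
                cols["sex"] = s.astype(float)
        else:
            cols[cov] = pheno[cov].astype(float)
    return pd.DataFrame(cols, index=pheno.index)


def residualize(
    pheno: pd.DataFrame,
    trait_col: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.Series:
    """OLS residuals of ``trait_col`` on an intercept plus ``covariates``.

    Rows with any missing value are dropped (listwise, logged); the
    returned Series is indexed like ``pheno`` with NaN for dropped rows.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    X = _design(pheno, tuple(covariates))
    y = pheno[trait_col].astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("residualize(%s): dropping %d incomplete rows", trait_col, dropped)
    Xk = sm.add_constant(X.loc[keep], has_constant="add")
    rank = np.linalg.matrix_rank(Xk.to_numpy())
    if rank < Xk.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        arr = Xk.to_numpy()
        for j, name in enumerate(Xk.columns):
            if name == "const":
                continue
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    fit = sm.OLS(y.loc[keep], Xk).fit()
    out = pd.Series(np.nan, index=pheno.index, name=f"{trait_col}_resid")
    out.loc[keep] = fit.resid
    return out


def founder_pca(
    gm,
    pedigrees,
    n_components: int = 10,
) -> pd.DataFrame:
    """Convenience genotype PCA: fit on founders, project everyone.

    PCA is computed on centered/scaled founder dosages and all individuals
    are projected onto the founder axes, so within-family structure does
    not distort the components. This is a pragmatic utility — *not* the
    FamCC family-data PC algorithm; externally computed PCs can always be
    supplied as phenotype columns instead.
    """
    founder_rows = [
        gm.sample_index(fid, iid)
        for fid, ped in pedigrees.items()
        for iid in ped.founders
        if (fid, iid) in gm._sample_index
    ]
    dose = gm.dosage()
    dose = np.where(np.isnan(dose), np.nanmean(dose, axis=0), dose)
    fd = dose[founder_rows]
    mean = fd.mean(axis=0)
    sd = fd.std(axis=0)
    keep = sd > 0
    z_f = (fd[:, keep] - mean[keep]) / sd[keep]
    z_all = (dose[:, keep] - mean[keep]) / sd[keep]
    _, _, vt = np.linalg.svd(z_f, full_matrices=False)
    k = min(n_components, vt.shape[0])
    proj = z_all @ vt[:k].T
    return pd.DataFrame(
        proj,
        columns=[f"pc{i + 1}" for i in range(k)],
        index=pd.MultiIndex.from_tuples(gm.samples, names=["family_id", "individual_id"]),
    )
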