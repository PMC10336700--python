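"""Data-driven EVPI pipeline for a parallel 3-arm trial.

Per-patient net benefit is ``qaly * wtp - cost``.  Arm means of NB are
asymptotically normal; with independent arms sharing a reference, the two
incremental mean NBs are bivariate normal with

    mu_i  = mean_nb(arm_i) - mean_nb(ref)
    sig_i^2 = var_of_mean(arm_i) + var_of_mean(ref)
    rho   = var_of_mean(ref) / (sig_1 * sig_2)

(the covariance is induced solely by the shared reference arm).  EVPI is then
available in closed form via the 2-D UNLI, or by stratified bootstrap
(E-max-minus-max-E over resampled arm mean NBs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from bivoi.core_unli import BVNParams, evpi_from_bvn

__all__ = [
    "PatientRecord",
    "TrialDataset",
    "ArmSummary",
    "EVPICurve",
    "PooledEstimate",
    "patient_nb",
    "arm_summaries",
    "incremental_nb_params",
    "evpi_unli",
    "evpi_bootstrap",
    "rubin_pool",
    "wtp_sweep",
    "plot_evpi_curve",
]

CSV_COLUMNS = ["patient_id", "arm", "cost", "qaly"]

#: Accepted missing-data policies for analyses that need complete data.
MISSING_POLICIES = ("error", "complete-case", "mean-impute")


@dataclass(frozen=True)
class PatientRecord:
    """One patient: arm label plus (possibly missing) cost and QALY."""

    patient_id: str
    arm: str
    cost: float | None = None
    qaly: float | None = None

    def is_complete(self) -> bool:
        return (
            self.cost is not None
            and self.qaly is not None
            and not math.isnan(self.cost)
            and not math.isnan(self.qaly)
        )


def patient_nb(record: PatientRecord, wtp: float) -> float:
    """Net benefit ``qaly * wtp - cost`` for one patient."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    if not record.is_complete():
        raise ValueError(
            f"patient {record.patient_id!r} has missing cost/qaly; "
            "apply a missing-data policy first"
        )
    return record.qaly * wtp - record.cost


@dataclass(frozen=True)
class TrialDataset:
    """Patient-level records of a parallel 3-arm trial.

    ``data`` holds columns patient_id, arm, cost, qaly (NaN = missing);
    ``arms`` is the ordered declared arm set and ``reference`` the designated
    reference arm.
    """

    data: pd.DataFrame
    arms: tuple[str, str, str]
    reference: str

    def __post_init__(self) -> None:
        missing_cols = [c for c in CSV_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"dataset is missing columns {missing_cols}")
        if len(self.arms) != 3 or len(set(self.arms)) != 3:
            raise ValueError(f"exactly 3 distinct arm names required, got {self.arms}")
        if self.reference not in self.arms:
            raise ValueError(f"reference {self.reference!r} not among arms {self.arms}")
        seen = set(self.data["arm"])
        unknown = seen - set(self.arms)
        if unknown:
            raise ValueError(f"records carry undeclared arm labels {sorted(unknown)}")
        empty = [a for a in self.arms if a not in seen]
        if empty:
            raise ValueError(f"arms {empty} have no records")

    @classmethod
    def from_csv(cls, path: str | Path, arms: Sequence[str], reference: str) -> "TrialDataset":
        df = pd.read_csv(path, dtype={"patient_id": str, "arm": str})
        missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"{path}: missing required columns {missing_cols}")
        return cls(df[CSV_COLUMNS].copy(), tuple(arms), reference)

    def to_csv(self, path: str | Path) -> None:
        self.data[CSV_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_records(
        cls, records: Iterable[PatientRecord], arms: Sequence[str], reference: str
    ) -> "TrialDataset":
        df = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "arm": r.arm,
                    "cost": np.nan if r.cost is None else r.cost,
                    "qaly": np.nan if r.qaly is None else r.qaly,
                }
                for r in records
            ],
            columns=CSV_COLUMNS,
        )
        return cls(df, tuple(arms), reference)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for row in self.data.itertuples(index=False):
            out.append(
                PatientRecord(
                    patient_id=str(row.patient_id),
                    arm=str(row.arm),
                    cost=None if pd.isna(row.cost) else float(row.cost),
                    qaly=None if pd.isna(row.qaly) else float(row.qaly),
                )
            )
        return out

    def has_missing(self) -> bool:
        return bool(self.data[["cost", "qaly"]].isna().any().any())

    def with_reference(self, reference: str) -> "TrialDataset":
        return replace(self, reference=reference)

    def resolve_missing(self, policy: str = "error") -> "TrialDataset":
        """Return a complete-data view under the chosen policy.

        ``error`` refuses missing cells; ``complete-case`` drops incomplete
        patients; ``mean-impute`` fills each missing cell with its arm mean
        (a simple stand-in — proper multiple imputation is out of scope, but
        :func:`rubin_pool` accepts externally produced per-imputation
        estimates).
        """
        if policy not in MISSING_POLICIES:
            raise ValueError(f"unknown missing-data policy {policy!r}; use one of {MISSING_POLICIES}")
        if not self.has_missing():
            return self
        if policy == "error":
            bad = self.data.loc[self.data[["cost", "qaly"]].isna().any(axis=1), "patient_id"]
            raise ValueError(
                f"{len(bad)} records have missing cost/qaly (e.g. patient "
                f"{bad.iloc[0]!r}); choose policy 'complete-case' or 'mean-impute'"
            )
        df = self.data.copy()
        if policy == "complete-case":
            df = df.dropna(subset=["cost", "qaly"]).reset_index(drop=True)
        else:
            for col in ("cost", "qaly"):
                df[col] = df[col].fillna(df.groupby("arm")[col].transform("mean"))
        return replace(self, data=df)


@dataclass(frozen=True)
class ArmSummary:
    """Mean net benefit of one arm with the variance of that mean."""

    arm: str
    n: int
    mean_nb: float
    var_of_mean: float


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-pooled mean vector and covariance across m imputations."""

    mean_vector: np.ndarray
    covariance: np.ndarray
    m: int


@dataclass(frozen=True)
class EVPICurve:
    """EVPI by method over a willingness-to-pay grid."""

    points: pd.DataFrame = field(repr=False)  # columns: wtp, evpi_unli, evpi_boot, boot_se

    def __post_init__(self) -> None:
        required = {"wtp", "evpi_unli", "evpi_boot", "boot_se"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"curve frame must have columns {sorted(required)}")

    def to_records(self) -> list[dict]:
        return self.points.to_dict(orient="records")


def _nb_by_arm(d: TrialDataset, wtp: float) -> dict[str, np.ndarray]:
    """Per-patient NB vectors keyed by arm; refuses missing data."""
    if wtp < 0:
        raise ValueError(f"wtp must be >= 0, got {wtp}")
    if d.has_missing():
        d.resolve_missing("error")  # raises with a named offending record
    nb = d.data["qaly"].to_numpy() * wtp - d.data["cost"].to_numpy()
    arm = d.data["arm"].to_numpy()
    return {a: nb[arm == a] for a in d.arms}


def arm_summaries(d: TrialDataset, wtp: float) -> list[ArmSummary]:
    """Mean NB and variance-of-mean for every arm, in declared arm order."""
    out = []
    for a, v in _nb_by_arm(d, wtp).items():
        if len(v) < 2:
            raise ValueError(f"arm {a!r} has n={len(v)} < 2; variance undefined")
        out.append(
            ArmSummary(
                arm=a,
                n=len(v),
                mean_nb=float(v.mean()),
                var_of_mean=float(v.var(ddof=1) / len(v)),
            )
        )
    return out


def incremental_nb_params(d: TrialDataset, wtp: float) -> BVNParams:
    """Bivariate-normal parameters of the two incremental mean NBs.

    Arms are independent; the correlation between the two incremental NBs is
    induced solely by the shared reference arm.
    """
    summaries = {s.arm: s for s in arm_summaries(d, wtp)}
    ref = summaries[d.reference]
    others = [summaries[a] for a in d.arms if a != d.reference]
    sig = [math.sqrt(s.var_of_mean + ref.var_of_mean) for s in others]
    return BVNParams(
        mu1=others[0].mean_nb - ref.mean_nb,
        mu2=others[1].mean_nb - ref.mean_nb,
        sigma1=sig[0],
        sigma2=sig[1],
        rho=ref.var_of_mean / (sig[0] * sig[1]),
    )


def evpi_unli(d: TrialDataset, wtp: float) -> float:
    """Closed-form EVPI via the 2-D UNLI of the incremental-NB parameters."""
    return evpi_from_bvn(incremental_nb_params(d, wtp))


def evpi_bootstrap(
    d: TrialDataset, wtp: float, B: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Bootstrap EVPI with its Monte-Carlo standard error.

    ``B`` stratified resamples (within arm, with replacement, original arm
    sizes); per resample the arm mean NBs; then
    ``EVPI = mean_b[max_k mean_nb_k^(b)] - max_k[mean_b mean_nb_k^(b)]``.
    The SE is the MC standard error of the first term.
    """
    B = int(B)
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    nb = _nb_by_arm(d, wtp)
    rng = np.random.default_rng(seed)
    boot_means = np.empty((B, len(d.arms)))
    for j, a in enumerate(d.arms):
        v = nb[a]
        idx = rng.integers(0, len(v), size=(B, len(v)))
        boot_means[:, j] = v[idx].mean(axis=1)
    best_per_rep = boot_means.max(axis=1)
    evpi = float(best_per_rep.mean() - boot_means.mean(axis=0).max())
    se = float(best_per_rep.std(ddof=1) / np.sqrt(B))
    return evpi, se


def rubin_pool(
    estimates: Sequence[tuple[np.ndarray, np.ndarray]]
) -> PooledEstimate:
    """Pool per-imputation (mean vector, covariance) pairs by Rubin's rules.

    Pooled mean is the element-wise average; pooled covariance is
    ``W + (1 + 1/m) * B`` with ``W`` the average within-imputation covariance
    and ``B`` the between-imputation covariance of the mean vectors.
    """
    if len(estimates) < 2:
        raise ValueError("rubin_pool needs at least 2 imputation estimates")
    means = np.asarray([np.asarray(mv, dtype=float) for mv, _ in estimates])
    covs = np.asarray([np.asarray(cv, dtype=float) for _, cv in estimates])
    m, dim = means.shape
    if covs.shape != (m, dim, dim):
        raise ValueError(
            f"covariance shapes {covs.shape} inconsistent with {m} mean vectors of dim {dim}"
        )
    pooled_mean = means.mean(axis=0)
    within = covs.mean(axis=0)
    centered = means - pooled_mean
    between = centered.T @ centered / (m - 1)
    return PooledEstimate(
        mean_vector=pooled_mean,
        covariance=within + (1.0 + 1.0 / m) * between,
        m=m,
    )


def wtp_sweep(
    d: TrialDataset,
    wtp_grid: Sequence[float],
    B: int = 1000,
    seed: int = 0,
) -> EVPICurve:
    """Closed-form and bootstrap EVPI over an increasing WTP grid."""
    grid = [float(w) for w in wtp_grid]
    if not grid:
        raise ValueError("wtp grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("wtp grid must be strictly increasing")
    rows = []
    for i, w in enumerate(grid):
        boot, se = evpi_bootstrap(d, w, B=B, seed=seed + i)
        rows.append(
            {"wtp": w, "evpi_unli": evpi_unli(d, w), "evpi_boot": boot, "boot_se": se}
        )
    return EVPICurve(points=pd.DataFrame(rows, columns=["wtp", "evpi_unli", "evpi_boot", "boot_se"]))


def plot_evpi_curve(curve: EVPICurve, path: str | Path) -> None:
    """Write the EVPI-vs-WTP figure (closed form solid, bootstrap dashed)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    pts = curve.points
    ax.plot(pts["wtp"], pts["evpi_unli"], "-", color="black", label="closed-form UNLI")
    ax.plot(pts["wtp"], pts["evpi_boot"], "--", color="black", label="bootstrap")
    ax.set_xlabel("Willingness-to-pay per QALY")
    ax.set_ylabel("EVPI")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
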