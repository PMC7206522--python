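"""Synthetic daily-diary cohort generator with known VAR ground truth.

Simulated patients carry a latent bivariate process — one sleep variable in
minutes (time in bed) and one depression core-symptom score on a 0–10 scale —
generated by a stationary VAR(p) with optional linear trend, Gaussian
innovations, and missing-completely-at-random diary days.  The latent values
are rendered as raw morning/evening diary logs (bed and rise clock times,
self-reported sleep minutes, two 0–10 depression items) so that the full
ingestion → preprocessing → VAR pipeline can be exercised against a known
truth.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SyntheticTruth",
    "RawDiaryLog",
    "PatientSimulation",
    "CohortRanges",
    "companion_matrix",
    "spectral_radius",
    "simulate_var",
    "default_truth",
    "generate_patient",
    "generate_cohort",
    "logs_to_frame",
    "write_cohort",
]

#: instrument bounds: diary sleep in minutes per day, depression VAS score
SLEEP_BOUNDS = (0.0, 1440.0)
SCORE_BOUNDS = (0.0, 10.0)

#: hard cap on MCAR missingness, mirroring the cohort exclusion rule
MAX_MISSING_PROB = 0.30


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of one simulated patient's bivariate VAR(p).

    Variable order is fixed as (sleep minutes, depression score).  The
    element ``coef_matrices[k][i, j]`` is the effect of variable ``j`` at
    ``t - (k+1)`` on variable ``i`` at ``t``.
    """

    patient_id: str
    n_days: int
    lag_order: int
    intercepts: np.ndarray          # (2,) minutes, score units
    coef_matrices: np.ndarray       # (p, 2, 2)
    resid_cov: np.ndarray           # (2, 2) innovation covariance
    trend_slopes: np.ndarray = field(default_factory=lambda: np.zeros(2))
    missing_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float).reshape(2)
        self.coef_matrices = np.asarray(self.coef_matrices, dtype=float)
        if self.coef_matrices.ndim == 2:
            self.coef_matrices = self.coef_matrices[None]
        self.coef_matrices = self.coef_matrices.reshape(self.lag_order, 2, 2)
        self.resid_cov = np.asarray(self.resid_cov, dtype=float).reshape(2, 2)
        self.trend_slopes = np.asarray(self.trend_slopes, dtype=float).reshape(2)

    def validate(self) -> None:
        if self.lag_order < 1:
            raise ValueError("lag_order must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        rho = spectral_radius(self.coef_matrices)
        if rho >= 1.0:
            raise ValueError(
                f"non-stationary coefficient matrices: companion spectral "
                f"radius {rho:.4f} >= 1"
            )
        if not np.allclose(self.resid_cov, self.resid_cov.T):
            raise ValueError("resid_cov must be symmetric")
        if np.linalg.eigvalsh(self.resid_cov).min() <= 0:
            raise ValueError("resid_cov must be positive definite")
        if not 0.0 <= self.missing_prob <= MAX_MISSING_PROB:
            raise ValueError(
                f"missing_prob {self.missing_prob} outside [0, "
                f"{MAX_MISSING_PROB}] (cohort exclusion bound)"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("intercepts", "coef_matrices", "resid_cov", "trend_slopes"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(**d)


@dataclass
class RawDiaryLog:
    """One patient-day of raw diary entries.

    Morning log: ``go_to_bed``/``get_up`` clock times (HH:MM, the interval may
    cross midnight) and self-reported ``sleep_minutes``.  Evening log: the two
    0–10 depression items (interest/pleasure; depressed/hopeless).  A missed
    log blanks all of its fields.
    """

    patient_id: str
    date: _dt.date
    go_to_bed: str | None
    get_up: str | None
    sleep_minutes: int | None
    item_interest: float | None
    item_mood: float | None


@dataclass
class PatientSimulation:
    """Diary logs plus the latent truth they were rendered from."""

    truth: SyntheticTruth
    logs: list[RawDiaryLog]
    latent_tib: np.ndarray      # (n_days,) minutes, post rounding/clipping
    latent_tst: np.ndarray
    latent_dep: np.ndarray      # (n_days,) score, post rounding/clipping
    clipped_fraction: float


def companion_matrix(coef_matrices: np.ndarray) -> np.ndarray:
    """Stack the (p, k, k) lag matrices into the kp × kp companion form."""
    A = np.asarray(coef_matrices, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, k, _ = A.shape
    comp = np.zeros((k * p, k * p))
    comp[:k, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return comp


def spectral_radius(coef_matrices: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(companion_matrix(coef_matrices))).max())


def simulate_var(
    intercepts: np.ndarray,
    coef_matrices: np.ndarray,
    resid_cov: np.ndarray,
    n: int,
    rng: np.random.Generator,
    burn: int = 300,
) -> np.ndarray:
    """Draw ``n`` observations from a stationary VAR with Gaussian innovations.

    The chain starts at the unconditional mean and a ``burn``-in is discarded
    so the output is (to numerical accuracy) a draw from the stationary law.
    """
    A = np.asarray(coef_matrices, dtype=float)
    if A.ndim == 2:
        A = A[None]
    p, k, _ = A.shape
    c = np.asarray(intercepts, dtype=float).reshape(k)
    mean = np.linalg.solve(np.eye(k) - A.sum(axis=0), c)
    chol = np.linalg.cholesky(np.asarray(resid_cov, dtype=float))
    total = n + burn
    eps = rng.standard_normal((total, k)) @ chol.T
    y = np.empty((total + p, k))
    y[:p] = mean
    for t in range(total):
        acc = c + eps[t]
        for lag in range(p):
            acc = acc + A[lag] @ y[p + t - 1 - lag]
        y[p + t] = acc
    return y[p + burn:]


def default_truth(
    patient_id: str = "sim-001",
    n_days: int = 170,
    missing_prob: float = 0.10,
    seed: int = 0,
    cross_std: tuple[float, float] = (0.0, 0.0),
) -> SyntheticTruth:
    """A realistic single-patient truth: TIB around 8 h, depression around 5.

    ``cross_std`` gives the standardized cross-lag coefficients
    (sleep→depression, depression→sleep); they are converted to raw units
    using the innovation SDs so that e.g. 0.3 means a 1-SD sleep shock moves
    next-day depression by 0.3 of its innovation SD.
    """
    sd = np.array([45.0, 1.2])  # innovation SDs: minutes, score units
    diag = np.array([0.35, 0.35])
    b_s2d, b_d2s = cross_std
    A1 = np.array(
        [
            [diag[0], b_d2s * sd[0] / sd[1]],
            [b_s2d * sd[1] / sd[0], diag[1]],
        ]
    )
    means = np.array([480.0, 5.0])
    intercepts = (np.eye(2) - A1) @ means
    resid_cov = np.diag(sd**2)
    return SyntheticTruth(
        patient_id=patient_id,
        n_days=n_days,
        lag_order=1,
        intercepts=intercepts,
        coef_matrices=A1[None],
        resid_cov=resid_cov,
        missing_prob=missing_prob,
        seed=seed,
    )


def _fmt_clock(minute_of_day: int) -> str:
    return f"{(minute_of_day // 60) % 24:02d}:{minute_of_day % 60:02d}"


def generate_patient(
    truth: SyntheticTruth,
    start_date: _dt.date = _dt.date(2023, 1, 1),
    sleep_efficiency: tuple[float, float] = (0.85, 0.97),
    bed_window: tuple[int, int] = (21 * 60, 24 * 60 + 59),
    burn: int = 300,
) -> PatientSimulation:
    """Render one patient's diary logs from their ground-truth VAR.

    The latent sleep value becomes the derived time in bed: a go-to-bed clock
    time is drawn uniformly in the evening window and the get-up time is
    back-computed so that the bed interval equals the latent value rounded to
    whole minutes.  Self-reported sleep minutes are a per-day efficiency
    fraction of time in bed.  The depression score is rounded to two decimals
    and split into two items whose mean recovers it exactly.  Missing morning
    and evening logs are independent Bernoulli(``missing_prob``) events.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n = truth.n_days
    latent = simulate_var(
        truth.intercepts, truth.coef_matrices, truth.resid_cov, n, rng, burn=burn
    )
    latent = latent + np.arange(n)[:, None] * truth.trend_slopes[None, :]

    tib = latent[:, 0]
    dep = latent[:, 1]
    n_clipped = int(np.sum((tib < SLEEP_BOUNDS[0]) | (tib > SLEEP_BOUNDS[1])))
    n_clipped += int(np.sum((dep < SCORE_BOUNDS[0]) | (dep > SCORE_BOUNDS[1])))
    tib = np.clip(tib, *SLEEP_BOUNDS)
    dep = np.clip(dep, *SCORE_BOUNDS)

    # instrument resolution: whole minutes for the clock, 0.01 on the item mean;
    # a bed interval of 0 or a full 1440 min cannot be expressed by two clock times
    tib = np.clip(np.round(tib), 1.0, 1439.0)
    dep = np.round(dep, 2)

    eff = rng.uniform(*sleep_efficiency, size=n)
    tst = np.floor(eff * tib)

    bed_minutes = rng.integers(bed_window[0], bed_window[1] + 1, size=n)
    half_span = np.minimum(np.round(rng.uniform(0.0, 1.0, size=n), 2), np.minimum(dep, 10.0 - dep))
    half_span = np.round(half_span, 2)

    morning_missing = rng.random(n) < truth.missing_prob
    evening_missing = rng.random(n) < truth.missing_prob

    logs: list[RawDiaryLog] = []
    for t in range(n):
        date = start_date + _dt.timedelta(days=t)
        if morning_missing[t]:
            gtb = gup = None
            slept = None
        else:
            start = int(bed_minutes[t]) % 1440
            gtb = _fmt_clock(start)
            gup = _fmt_clock((start + int(tib[t])) % 1440)
            slept = int(tst[t])
        if evening_missing[t]:
            interest = mood = None
        else:
            interest = round(float(dep[t] + half_span[t]), 2)
            mood = round(float(dep[t] - half_span[t]), 2)
        logs.append(
            RawDiaryLog(
                patient_id=truth.patient_id,
                date=date,
                go_to_bed=gtb,
                get_up=gup,
                sleep_minutes=slept,
                item_interest=interest,
                item_mood=mood,
            )
        )
    return PatientSimulation(
        truth=truth,
        logs=logs,
        latent_tib=tib,
        latent_tst=tst,
        latent_dep=dep,
        clipped_fraction=n_clipped / (2 * n),
    )


@dataclass
class CohortRanges:
    """Sampling bounds for per-patient ground truths.

    Defaults emulate the study conditions: 143–205 consecutive diary days,
    time in bed around 7–8.5 h with innovation SD 30–60 min, depression
    around mid-scale with innovation SD about 1 score unit, moderate daily
    autocorrelation, small linear drifts, and roughly 10% missed logs.
    ``cross_std`` bounds the standardized cross-lag coefficients; the default
    cohort is uncoupled (both zero) so coupling is opt-in and known.
    """

    n_days: tuple[int, int] = (143, 205)
    lag_order: int = 1
    sleep_mean: tuple[float, float] = (430.0, 510.0)
    dep_mean: tuple[float, float] = (3.0, 7.0)
    sleep_sd: tuple[float, float] = (30.0, 60.0)
    dep_sd: tuple[float, float] = (0.8, 1.5)
    diag_coef: tuple[float, float] = (0.2, 0.5)
    cross_std: tuple[float, float] = (0.0, 0.0)
    resid_corr: tuple[float, float] = (-0.2, 0.2)
    trend_sleep: tuple[float, float] = (-0.1, 0.1)
    trend_dep: tuple[float, float] = (-0.005, 0.005)
    missing_prob: tuple[float, float] = (0.05, 0.15)


def _draw_truth(
    pid: str, ranges: CohortRanges, rng: np.random.Generator, max_attempts: int = 100
) -> SyntheticTruth:
    for _ in range(max_attempts):
        sd = np.array([rng.uniform(*ranges.sleep_sd), rng.uniform(*ranges.dep_sd)])
        diag = rng.uniform(*ranges.diag_coef, size=2)
        b_s2d = rng.uniform(*ranges.cross_std)
        b_d2s = rng.uniform(*ranges.cross_std)
        A1 = np.array(
            [
                [diag[0], b_d2s * sd[0] / sd[1]],
                [b_s2d * sd[1] / sd[0], diag[1]],
            ]
        )
        if spectral_radius(A1[None]) >= 0.97:
            continue
        means = np.array(
            [rng.uniform(*ranges.sleep_mean), rng.uniform(*ranges.dep_mean)]
        )
        corr = rng.uniform(*ranges.resid_corr)
        cov = np.array(
            [[sd[0] ** 2, corr * sd[0] * sd[1]], [corr * sd[0] * sd[1], sd[1] ** 2]]
        )
        return SyntheticTruth(
            patient_id=pid,
            n_days=int(rng.integers(ranges.n_days[0], ranges.n_days[1] + 1)),
            lag_order=ranges.lag_order,
            intercepts=(np.eye(2) - A1) @ means,
            coef_matrices=A1[None],
            resid_cov=cov,
            trend_slopes=np.array(
                [rng.uniform(*ranges.trend_sleep), rng.uniform(*ranges.trend_dep)]
            ),
            missing_prob=float(rng.uniform(*ranges.missing_prob)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    raise RuntimeError(
        f"could not draw a stationary truth for {pid} in {max_attempts} attempts; "
        "narrow the coefficient ranges"
    )


def generate_cohort(
    n_patients: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
) -> tuple[list[list[RawDiaryLog]], list[SyntheticTruth]]:
    """Draw ``n_patients`` independent truths and render their diary logs."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    truths = [
        _draw_truth(f"sim-{i + 1:03d}", ranges, rng) for i in range(n_patients)
    ]
    logs = [generate_patient(t).logs for t in truths]
    return logs, truths


def logs_to_frame(logs: list[RawDiaryLog]):
    """Flatten diary logs into the canonical long CSV layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in logs],
            "date": [r.date.isoformat() for r in logs],
            "go_to_bed": [r.go_to_bed for r in logs],
            "get_up": [r.get_up for r in logs],
            "sleep_minutes": [r.sleep_minutes for r in logs],
            "item_interest": [r.item_interest for r in logs],
            "item_mood": [r.item_mood for r in logs],
        }
    )


def write_cohort(
    logs: list[list[RawDiaryLog]],
    truths: list[SyntheticTruth],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write the cohort as ``diary.csv`` plus a YAML ground-truth sidecar."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.concat([logs_to_frame(lg) for lg in logs], ignore_index=True)
    csv_path = out_dir / "diary.csv"
    frame.to_csv(csv_path, index=False)
    yaml_path = out_dir / "truths.yaml"
    with open(yaml_path, "w") as fh:
        yaml.safe_dump([t.to_dict() for t in truths], fh, sort_keys=False)
    return csv_path, yaml_path
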