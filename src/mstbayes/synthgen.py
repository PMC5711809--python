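"""Synthetic outlier-contaminated titration datasets with known ground truth.

Each simulated experiment consists of ``repeats`` independent serial-dilution
series.  For every series the *realized* concentrations (with pipetting
noise) drive the mass-action response, normal measurement noise is added at
the response level, and then a fixed fraction of all points — 20% by default
— is replaced by draws from a uniform distribution spanning the U–B response
range plus a margin, emulating the anomalous observations ("outliers") that
plague real thermophoresis data.  The analyst-facing x-coordinate of every
point is the *targeted* concentration: the concentration error is a hidden
corruption, exactly as in a real experiment.

``TABLE_CASES`` holds the ten benchmark generator configurations used by the
simulation study (K_D from 0.05 to 5 µM, pipette volume std 0.1–2 µl on a
10 µl transfer, 1–10 repeats, response noise sd 0.5–2).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import BindingParams, mass_action_response
from .dilution import DEFAULT_N_STEPS, PipetteSpec, simulate_dilution_series

__all__ = [
    "TestCaseParams",
    "TitrationDataset",
    "TABLE_CASES",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

#: Targeted volume (µl) of each pipetting event in the benchmark cases.
TABLE_TARGET_VOLUME_UL = 10.0

#: Default labelled-partner concentration (nM) for simulated experiments.
DEFAULT_C_FL_NM = 50.0

REQUIRED_COLUMNS = ("replicate", "concentration_nM", "response")
OPTIONAL_COLUMNS = ("true_concentration_nM", "is_outlier")


@dataclass(frozen=True)
class TestCaseParams:
    """Ground-truth generator settings for one synthetic test case.

    Concentrations in nM; ``noise_sd`` in response units; ``pipette_cov`` is
    the dimensionless CoV of each pipetted volume.  ``c_starting`` defaults
    to ``100 * kd_true`` so the 16-point two-fold series brackets K_D, and
    ``c_fl_true`` defaults to 50 nM.
    """

    __test__ = False  # "Test" here means benchmark test case, not a pytest class

    kd_true: float
    b_true: float
    u_true: float
    noise_sd: float = 1.0
    pipette_cov: float = 0.01
    repeats: int = 3
    c_fl_true: float = DEFAULT_C_FL_NM
    c_starting: float | None = None
    n_steps: int = DEFAULT_N_STEPS
    outlier_fraction: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")
        for name in ("kd_true", "c_fl_true"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.c_starting is not None and not self.c_starting > 0:
            raise ValueError("c_starting must be positive")
        if self.noise_sd < 0 or self.pipette_cov < 0:
            raise ValueError("noise_sd and pipette_cov must be non-negative")

    @property
    def stock_concentration(self) -> float:
        """Stock ligand concentration (nM); defaults to 100 x true K_D."""
        return self.c_starting if self.c_starting is not None else 100.0 * self.kd_true

    @property
    def binding_params(self) -> BindingParams:
        return BindingParams(kd=self.kd_true, u=self.u_true, b=self.b_true, c_fl=self.c_fl_true)


def _case(kd_um: float, b: float, u: float, sd: float, cov_ul: float, repeats: int, seed: int) -> TestCaseParams:
    return TestCaseParams(
        kd_true=kd_um * 1e3,
        b_true=b,
        u_true=u,
        noise_sd=sd,
        pipette_cov=cov_ul / TABLE_TARGET_VOLUME_UL,
        repeats=repeats,
        rng_seed=seed,
    )


#: The ten benchmark generator configurations (1-based case number = index + 1).
TABLE_CASES: tuple[TestCaseParams, ...] = (
    _case(5.0, 780, 800, 1.0, 0.1, 3, 1),
    _case(0.5, 780, 800, 1.0, 0.1, 3, 2),
    _case(0.1, 780, 800, 1.0, 0.1, 3, 3),
    _case(0.05, 780, 800, 1.0, 0.1, 3, 4),
    _case(0.5, 795, 800, 1.0, 0.1, 3, 5),
    _case(5.0, 780, 800, 1.0, 0.2, 3, 6),
    _case(5.0, 780, 800, 1.0, 0.1, 1, 7),
    _case(5.0, 780, 800, 1.0, 0.1, 10, 8),
    _case(5.0, 780, 800, 0.5, 0.1, 3, 9),
    _case(5.0, 780, 800, 2.0, 0.1, 3, 10),
)

#: Margin factor of the outlier uniform beyond the |B - U| range.
OUTLIER_MARGIN_FACTOR = 0.25


@dataclass
class TitrationDataset:
    """Replicate-structured (concentration, response) observations.

    ``data`` columns: ``replicate`` (contiguous integers from 1),
    ``concentration_nM`` (the analyst-facing, targeted concentration),
    ``response``, and for synthetic data optionally ``true_concentration_nM``
    and ``is_outlier``.  ``ground_truth`` carries the generator settings for
    synthetic datasets and is ``None`` for experimental data.
    """

    data: pd.DataFrame
    ground_truth: TestCaseParams | None = None

    def __post_init__(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"dataset is missing required column {col!r}")
        if len(df) == 0:
            raise ValueError("dataset has no points")
        if not np.all(df["concentration_nM"].to_numpy() > 0):
            raise ValueError("all concentrations must be positive")
        if not np.all(np.isfinite(df["response"].to_numpy())):
            raise ValueError("all responses must be finite")
        reps = np.unique(df["replicate"].to_numpy())
        if not np.array_equal(reps, np.arange(1, len(reps) + 1)):
            raise ValueError("replicate ids must be contiguous integers starting at 1")

    @property
    def concentrations(self) -> np.ndarray:
        return self.data["concentration_nM"].to_numpy(dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return self.data["response"].to_numpy(dtype=float)

    @property
    def n_points(self) -> int:
        return len(self.data)

    @property
    def replicate_ids(self) -> np.ndarray:
        return np.unique(self.data["replicate"].to_numpy())

    def with_responses(self, responses: np.ndarray) -> "TitrationDataset":
        """Copy of the dataset with the response column replaced."""
        df = self.data.copy()
        df["response"] = np.asarray(responses, dtype=float)
        return TitrationDataset(data=df, ground_truth=self.ground_truth)


def generate_dataset(params: TestCaseParams) -> TitrationDataset:
    """Simulate one outlier-contaminated titration experiment.

    Per repeat a fresh dilution series is drawn; responses are the
    mass-action curve at the *realized* concentrations plus
    ``Normal(0, noise_sd)`` noise (the noise does not scale with dilution
    step).  Then exactly ``floor(outlier_fraction * N)`` points, chosen
    uniformly without replacement over the pooled dataset, are replaced by
    ``Uniform(min(U,B) - m, max(U,B) + m)`` draws with margin
    ``m = 0.25 * |B - U|``.  Deterministic given ``params.rng_seed``.
    """
    rng = np.random.default_rng(params.rng_seed)
    pipette = PipetteSpec(target_volume=TABLE_TARGET_VOLUME_UL, cov=params.pipette_cov)
    frames = []
    for rep in range(1, params.repeats + 1):
        series = simulate_dilution_series(params.stock_concentration, params.n_steps, pipette, rng)
        true_c = series.concentrations
        resp = mass_action_response(true_c, params.binding_params)
        if params.noise_sd > 0:
            resp = resp + rng.normal(0.0, params.noise_sd, size=true_c.size)
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "concentration_nM": series.targeted,
                    "response": resp,
                    "true_concentration_nM": true_c,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)

    n_out = int(np.floor(params.outlier_fraction * len(df)))
    is_outlier = np.zeros(len(df), dtype=bool)
    if n_out > 0:
        idx = rng.choice(len(df), size=n_out, replace=False)
        lo, hi = sorted((params.u_true, params.b_true))
        margin = OUTLIER_MARGIN_FACTOR * (hi - lo)
        df.loc[idx, "response"] = rng.uniform(lo - margin, hi + margin, size=n_out)
        is_outlier[idx] = True
    df["is_outlier"] = is_outlier
    return TitrationDataset(data=df, ground_truth=params)


_GT_PREFIX = "# ground_truth: "


def save_dataset(dataset: TitrationDataset, path: str | Path) -> None:
    """Write a dataset as UTF-8 CSV; generator settings go into a '#' header line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if dataset.ground_truth is not None:
            fh.write(_GT_PREFIX + json.dumps(asdict(dataset.ground_truth)) + "\n")
        dataset.data.to_csv(fh, index=False)


def load_dataset(path: str | Path) -> TitrationDataset:
    """Read a titration dataset CSV written by :func:`save_dataset` (or by hand).

    Required columns: replicate, concentration_nM, response.  Unknown columns
    are preserved.  Raises ``ValueError`` naming the offending line on
    malformed input.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    ground_truth = None
    lines = text.splitlines()
    body_lines = []
    for line in lines:
        if line.startswith(_GT_PREFIX):
            ground_truth = TestCaseParams(**json.loads(line[len(_GT_PREFIX):]))
        elif line.startswith("#") or not line.strip():
            continue
        else:
            body_lines.append(line)
    if not body_lines:
        raise ValueError(f"{path}: file contains no data rows")
    try:
        df = pd.read_csv(io.StringIO("\n".join(body_lines)))
    except Exception as exc:  # pandas raises several parser error types
        raise ValueError(f"{path}: could not parse CSV: {exc}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n_header = 1 + (ground_truth is not None)
    for i, (_, row) in enumerate(df.iterrows()):
        if not np.isfinite(row["concentration_nM"]) or row["concentration_nM"] <= 0:
            raise ValueError(f"{path}: non-positive concentration on data line {i + 1 + n_header}")
        if not np.isfinite(row["response"]):
            raise ValueError(f"{path}: non-finite response on data line {i + 1 + n_header}")
    if "is_outlier" in df.columns:
        df["is_outlier"] = df["is_outlier"].astype(bool)
    return TitrationDataset(data=df, ground_truth=ground_truth)
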