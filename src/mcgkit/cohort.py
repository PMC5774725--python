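"""Feature-level cohort generation.

Draws per-subject vectors of the 10 magnetic-field-map predictors from
group-conditional (multivariate) normal distributions, so that downstream
group comparison and rule-out modelling can be exercised at study scale
without waveform simulation.  The packaged default scenario carries the
published group means +/- SD for the three study groups (70 ischemic
patients, 69 controls, 37 young healthy volunteers).

Predictors default to independent normals within each group; a correlation
matrix can be supplied.  Draws are not truncated: ratio-valued predictors
can in principle go nonpositive in the far tail (<0.3% for the most extreme
group), which is accepted so that sample moments are unbiased for the
scenario parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical predictor order used across the package.
PREDICTORS = (
    "QR_MMR",
    "QR_angle",
    "QR_interval",
    "QR_pd",
    "QR_peak",
    "RS_MMR",
    "RS_angle",
    "RS_interval",
    "RS_pd",
    "RS_peak",
)

#: Groups: A = patients (positive class), B/C = control groups.
GROUPS = ("A", "B", "C")


@dataclass
class GroupSpec:
    """Size and per-predictor (mean, sd) of one cohort group."""

    size: int
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("group size must be positive")
        missing = [p for p in PREDICTORS if p not in self.means or p not in self.sds]
        if missing:
            raise ValueError(f"group spec missing predictors: {missing}")
        if any(self.sds[p] < 0 for p in PREDICTORS):
            raise ValueError("SDs must be non-negative")

    def mean_vector(self) -> np.ndarray:
        return np.array([self.means[p] for p in PREDICTORS])

    def sd_vector(self) -> np.ndarray:
        return np.array([self.sds[p] for p in PREDICTORS])


@dataclass
class CohortScenario:
    """Cohort composition for the feature-level generator.

    ``correlation`` (optional) is a common 10 x 10 predictor correlation
    matrix applied within every group; it must be symmetric positive
    semi-definite with unit diagonal.
    """

    groups: dict[str, GroupSpec]
    correlation: np.ndarray | None = None
    seed: int | None = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("scenario needs at least one group")
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(PREDICTORS)
            if corr.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k}")
            if not np.allclose(corr, corr.T, atol=1e-10):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(corr).min() < -1e-10:
                raise ValueError("correlation matrix must be positive semi-definite")
            self.correlation = corr

    @property
    def total_size(self) -> int:
        return sum(g.size for g in self.groups.values())

    def with_sizes(self, **sizes: int) -> "CohortScenario":
        """Copy of the scenario with some group sizes replaced."""
        groups = {
            name: GroupSpec(sizes.get(name, spec.size), dict(spec.means), dict(spec.sds))
            for name, spec in self.groups.items()
        }
        return CohortScenario(groups, self.correlation, self.seed, self.name)


def study_scenario(seed: int | None = 0) -> CohortScenario:
    """The packaged default scenario: published group parameters and sizes."""
    raw = resources.files("mcgkit.data").joinpath("cohort_groups.json").read_text()
    return scenario_from_dict(json.loads(raw), seed=seed, name="study")


def scenario_from_dict(payload: dict, seed: int | None = 0, name: str = "custom") -> CohortScenario:
    groups = {}
    for gname, g in payload["groups"].items():
        pred = g["predictors"]
        groups[gname] = GroupSpec(
            size=int(g["size"]),
            means={p: float(pred[p][0]) for p in pred},
            sds={p: float(pred[p][1]) for p in pred},
        )
    corr = payload.get("correlation")
    return CohortScenario(
        groups=groups,
        correlation=None if corr is None else np.asarray(corr, dtype=float),
        seed=seed,
        name=name,
    )


def scenario_from_json(path: str | Path, seed: int | None = 0) -> CohortScenario:
    payload = json.loads(Path(path).read_text())
    return scenario_from_dict(payload, seed=seed, name=Path(path).stem)


def sample_feature_cohort(
    scenario: CohortScenario, seed: int | None = None
) -> pd.DataFrame:
    """Draw a per-subject feature table from ``scenario``.

    Returns a DataFrame with ``subject_id``, ``group`` and the 10 predictor
    columns, one row per subject.  ``seed`` overrides ``scenario.seed``;
    identical seeds give identical tables.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    k = len(PREDICTORS)
    if scenario.correlation is not None:
        # PSD square root; tolerates semi-definite matrices unlike Cholesky
        w, v = np.linalg.eigh(scenario.correlation)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    else:
        chol = np.eye(k)
    frames = []
    offset = 0
    for gname in sorted(scenario.groups):
        spec = scenario.groups[gname]
        z = rng.standard_normal(size=(spec.size, k)) @ chol.T
        x = spec.mean_vector()[None, :] + z * spec.sd_vector()[None, :]
        df = pd.DataFrame(x, columns=list(PREDICTORS))
        df.insert(0, "group", gname)
        df.insert(0, "subject_id", [f"{gname}{i + 1:03d}" for i in range(spec.size)])
        frames.append(df)
        offset += spec.size
    return pd.concat(frames, ignore_index=True)
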