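"""Synthetic resting-state cohorts with planted modular covariance.

The generator emulates a three-age-group rodent imaging study: per subject a
60-node x 600-timepoint ROI signal matrix drawn from a zero-mean multivariate
normal whose correlation structure is block-modular (four 15-node modules by
default), with the *between*-module coupling varying by group so that younger
groups are more modular.  Node series are L2-normalized, matching how ROI
signals are exported by the imaging pipeline; Pearson correlation is invariant
to that rescaling.  Toy behavior tables (open-field margin distance, daily
freezing counts, sucrose/water volumes) accompany each cohort so the whole
analysis chain is testable without in-vivo data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "DEFAULT_BEHAVIOR_EFFECTS",
    "block_covariance",
    "make_cohort",
    "behavior_tables",
    "write_cohort",
]

#: Default group labels: 10-, 30- and 60-week-old cohorts.
DEFAULT_GROUPS = ("10wo", "30wo", "60wo")

#: Group-varying between-module correlation; lower = more modular (young).
DEFAULT_RHO_BETWEEN = {"10wo": 0.05, "30wo": 0.10, "60wo": 0.15}


def _per_group(value, groups, name: str) -> dict:
    """Broadcast a scalar to all groups or validate a per-group mapping."""
    if isinstance(value, Mapping):
        missing = [g for g in groups if g not in value]
        if missing:
            raise ValueError(f"{name} missing groups: {missing}")
        return {g: float(value[g]) for g in groups}
    return {g: float(value) for g in groups}


@dataclass(frozen=True)
class CohortSpec:
    """Design parameters of a synthetic cohort.

    Parameters
    ----------
    groups
        Group labels (default three age groups).
    n_per_group
        Subjects per group (default 10, the study design).
    n_nodes, n_timepoints
        ROI count and timeseries length (defaults 60 and 600).
    module_sizes
        Planted module layout; must sum to ``n_nodes``.
    rho_within, rho_between
        Block correlations, scalar or per-group mapping.  Must satisfy
        ``0 <= rho_between < rho_within < 1`` and yield a positive
        semi-definite block covariance.
    noise_sd
        SD of additive i.i.d. Gaussian sensor noise on top of the
        multivariate-normal draw.
    seed
        Master seed; per-subject streams are spawned deterministically.
    """

    groups: Sequence[str] = DEFAULT_GROUPS
    n_per_group: int = 10
    n_nodes: int = 60
    n_timepoints: int = 600
    module_sizes: Sequence[int] = (15, 15, 15, 15)
    rho_within: float | Mapping[str, float] = 0.5
    rho_between: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RHO_BETWEEN)
    )
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.n_nodes < 2 or self.n_timepoints < 4:
            raise ValueError("need n_nodes >= 2 and n_timepoints >= 4")
        if any(m < 1 for m in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum {sum(self.module_sizes)} != n_nodes {self.n_nodes}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        rw = _per_group(self.rho_within, self.groups, "rho_within")
        rb = _per_group(self.rho_between, self.groups, "rho_between")
        for g in self.groups:
            if not 0 < rw[g] < 1:
                raise ValueError(f"rho_within[{g}]={rw[g]} outside (0,1)")
            if not 0 <= rb[g] < rw[g]:
                raise ValueError(
                    f"rho_between[{g}]={rb[g]} must lie in [0, rho_within={rw[g]})"
                )
        for g in self.groups:  # PSD check, raises if violated
            block_covariance(self, g)

    def rho_within_for(self, group: str) -> float:
        return _per_group(self.rho_within, self.groups, "rho_within")[group]

    def rho_between_for(self, group: str) -> float:
        return _per_group(self.rho_between, self.groups, "rho_between")[group]

    @property
    def planted_partition(self) -> np.ndarray:
        """Module affiliation vector implied by ``module_sizes`` (labels 1..M)."""
        return np.repeat(
            np.arange(1, len(self.module_sizes) + 1), self.module_sizes
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["module_sizes"] = list(self.module_sizes)
        if isinstance(d["rho_within"], Mapping):
            d["rho_within"] = dict(d["rho_within"])
        if isinstance(d["rho_between"], Mapping):
            d["rho_between"] = dict(d["rho_between"])
        return json.dumps(d, indent=2)


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    sex: str
    timeseries: np.ndarray  # (n_nodes, n_timepoints)
    planted_partition: np.ndarray  # (n_nodes,), labels 1..M


def block_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Planted block correlation matrix for one group.

    Unit diagonal, ``rho_within`` for same-module pairs and ``rho_between``
    otherwise.  Raises ``ValueError`` when the parameter combination is not
    positive semi-definite (smallest eigenvalue below ``-1e-10``).
    """
    rw = spec.rho_within_for(group)
    rb = spec.rho_between_for(group)
    labels = spec.planted_partition
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, rw, rb)
    np.fill_diagonal(cov, 1.0)
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < -1e-10:
        raise ValueError(
            f"block covariance for group {group!r} is not positive semi-definite "
            f"(min eigenvalue {min_eig:.3e}); reduce rho_within/rho_between"
        )
    return cov


def _covariance_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix (Cholesky; eigh fallback on the boundary)."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        return v * np.sqrt(np.clip(w, 0.0, None))


def make_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Draw a full cohort, deterministically given ``spec.seed``.

    Each subject's node x time matrix is ``L @ eps + noise``, with ``L`` the
    group covariance factor, followed by L2 normalization of every node
    series.  Sexes alternate within group (balanced design).
    """
    n_subjects = len(spec.groups) * spec.n_per_group
    streams = np.random.SeedSequence(spec.seed).spawn(n_subjects)
    subjects: list[SyntheticSubject] = []
    planted = spec.planted_partition
    idx = 0
    for group in spec.groups:
        chol = _covariance_factor(block_covariance(spec, group))
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(streams[idx])
            eps = rng.standard_normal((spec.n_nodes, spec.n_timepoints))
            ts = chol @ eps
            if spec.noise_sd > 0:
                ts = ts + spec.noise_sd * rng.standard_normal(ts.shape)
            ts /= np.linalg.norm(ts, axis=1, keepdims=True)
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{group}_s{i + 1:02d}",
                    group=group,
                    sex="F" if i % 2 == 0 else "M",
                    timeseries=ts,
                    planted_partition=planted.copy(),
                )
            )
            idx += 1
    return subjects


#: Per-group (mean, sd) for the toy behavior measures.  Directions mirror the
#: study's findings: young mice move more along cage margins; the oldest group
#: freezes most, and all groups retain fear memory on recall days.
DEFAULT_BEHAVIOR_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    "10wo": {
        "margin_distance_cm": (1500.0, 200.0),
        "freezing_counts_d1": (8.0, 3.0),
        "freezing_counts_d2": (14.0, 4.0),
        "freezing_counts_d3": (13.0, 4.0),
        "sucrose_ml": (6.0, 1.5),
        "water_ml": (2.0, 0.8),
    },
    "30wo": {
        "margin_distance_cm": (1100.0, 200.0),
        "freezing_counts_d1": (9.0, 3.0),
        "freezing_counts_d2": (13.0, 4.0),
        "freezing_counts_d3": (11.0, 4.0),
        "sucrose_ml": (6.0, 1.5),
        "water_ml": (2.0, 0.8),
    },
    "60wo": {
        "margin_distance_cm": (1000.0, 200.0),
        "freezing_counts_d1": (12.0, 4.0),
        "freezing_counts_d2": (15.0, 4.0),
        "freezing_counts_d3": (16.0, 4.0),
        "sucrose_ml": (5.5, 1.5),
        "water_ml": (2.2, 0.8),
    },
}


def behavior_tables(
    spec: CohortSpec,
    effect_params: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
) -> pd.DataFrame:
    """Toy behavior table: one row per subject, Gaussian draws truncated at 0.

    ``effect_params`` maps group -> measure -> (mean, sd); negative sds are
    rejected.  Freezing counts are rounded to nonnegative integers.  With the
    default effects, group labels without their own profile fall back to the
    reference (30wo) means.
    """
    if effect_params is not None:
        effects = effect_params
    else:
        effects = {
            g: DEFAULT_BEHAVIOR_EFFECTS.get(g, DEFAULT_BEHAVIOR_EFFECTS["30wo"])
            for g in spec.groups
        }
    measures = None
    for group in spec.groups:
        if group not in effects:
            raise ValueError(f"effect_params missing group {group!r}")
        keys = sorted(effects[group])
        if measures is None:
            measures = keys
        elif keys != measures:
            raise ValueError("effect_params groups disagree on measures")
        for name, (_, sd) in effects[group].items():
            if sd < 0:
                raise ValueError(f"negative sd for {group}/{name}")
    # independent stream per subject, offset from the timeseries streams
    streams = np.random.SeedSequence((spec.seed, 1)).spawn(
        len(spec.groups) * spec.n_per_group
    )
    rows = []
    idx = 0
    for group in spec.groups:
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(streams[idx])
            row: dict[str, object] = {
                "subject_id": f"{group}_s{i + 1:02d}",
                "group": group,
                "sex": "F" if i % 2 == 0 else "M",
            }
            for name in measures:
                mean, sd = effects[group][name]
                val = max(0.0, mean + sd * rng.standard_normal())
                if name.startswith("freezing_counts"):
                    val = int(round(val))
                row[name] = val
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


def write_cohort(
    subjects: Sequence[SyntheticSubject],
    spec: CohortSpec,
    out_dir: str | Path,
) -> Path:
    """Write per-subject TSV timeseries, a metadata CSV and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for s in subjects:
        np.savetxt(out / f"{s.subject_id}.tsv", s.timeseries, delimiter="\t")
        meta.append({"subject_id": s.subject_id, "group": s.group, "sex": s.sex})
    pd.DataFrame(meta).to_csv(out / "metadata.csv", index=False)
    (out / "cohort_spec.json").write_text(spec.to_json())
    return out
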