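"""Synthetic multi-dataset rs-fMRI cohort generator with known FC ground truth.

The generator emulates the hierarchical structure that the split analyses
exploit: a dataset holds NC and PD subjects, each subject contributes one
or more replicate scans, and every scan is a T x R multivariate-normal
timeseries whose cross-region correlation matrix is the subject's target
correlation perturbed by scan-level noise.

Group effects and all random effects live in Fisher-z space:

* a base correlation matrix (low-rank factor structure plus unit diagonal)
  is shared by everyone;
* PD subjects draw a disease subtype; each subtype shifts its own set of
  ROI pairs by a signed delta_z (tanh(atanh(c) + delta_z));
* subject- and scan-level Gaussian noise (sd sigma_subject, sigma_scan) is
  added to the off-diagonal z-entries;
* after every z-space perturbation the matrix is projected back to the
  nearest valid correlation matrix.

An optional AR(1) temporal filter is applied per region to correlated
innovations, which leaves the stationary cross-region correlation equal to
the target, so the FC ground truth stays exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pairs import PairIndex, pair_count
from .records import ROITimeseries, ScanRecord


class SimulationError(RuntimeError):
    pass


@dataclass
class EffectSpec:
    """One disease subtype: the pairs it shifts and the shared z-shift."""

    pairs: tuple[int, ...]
    delta_z: float

    def __post_init__(self) -> None:
        self.pairs = tuple(int(k) for k in self.pairs)


@dataclass
class SimConfig:
    """Full description of one synthetic dataset.

    ``effect_pairs`` lists one :class:`EffectSpec` per PD subtype and
    ``subtype_proportions`` their mixing weights (must sum to 1). Noise
    sigmas are Fisher-z-space standard deviations: ``sigma_subject`` for
    the subject-level random effect, ``sigma_scan`` for the replicate-scan
    level. ``ar1_coefficient`` in (-1, 1) switches on temporal
    autocorrelation (0 = white).
    """

    n_regions: int = 30
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    n_subjects_nc: int = 12
    n_subjects_pd: int = 12
    n_replicates: int = 2
    base_structure_rank: int = 5
    effect_pairs: tuple[EffectSpec, ...] = ()
    subtype_proportions: tuple[float, ...] = ()
    sigma_subject: float = 0.1
    sigma_scan: float = 0.05
    ar1_coefficient: float = 0.0
    seed: int = 0
    dataset_id: str = "sim"
    #: seed of the shared baseline correlation structure; defaults to ``seed``.
    #: Datasets meant to describe the same underlying population (e.g. for
    #: cross-dataset transfer) should share a base_seed while differing in seed.
    base_seed: int | None = None
    #: "random": each PD subject draws a subtype from subtype_proportions;
    #: "stratified": exact largest-remainder counts in shuffled order --
    #: removes composition noise in designed heterogeneity experiments.
    subtype_assignment: str = "random"

    def __post_init__(self) -> None:
        self.effect_pairs = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(*e) for e in self.effect_pairs
        )
        if not self.subtype_proportions and self.effect_pairs:
            n = len(self.effect_pairs)
            self.subtype_proportions = (1.0 / n,) * n
        self.subtype_proportions = tuple(float(w) for w in self.subtype_proportions)
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 1 <= self.base_structure_rank <= self.n_regions:
            raise ValueError("base_structure_rank must be in [1, n_regions]")
        if not -1 < self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in (-1, 1)")
        if min(self.sigma_subject, self.sigma_scan, 0.0) < 0:
            raise ValueError("noise sigmas must be nonnegative")
        if self.subtype_assignment not in ("random", "stratified"):
            raise ValueError("subtype_assignment must be 'random' or 'stratified'")
        if self.effect_pairs:
            if len(self.subtype_proportions) != len(self.effect_pairs):
                raise ValueError("one proportion per subtype required")
            if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
                raise ValueError("subtype_proportions must sum to 1")
            n_pairs = pair_count(self.n_regions)
            for e in self.effect_pairs:
                bad = [k for k in e.pairs if not 0 <= k < n_pairs]
                if bad:
                    raise ValueError(f"effect pair indices out of range: {bad}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    base_correlation: np.ndarray
    subtype_of_subject: dict[str, int]  # PD subjects only; -1 means NC
    effects: tuple[EffectSpec, ...]
    scan_target: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def affected_pairs(self) -> set[int]:
        return {k for e in self.effects for k in e.pairs}

    def to_json(self, path) -> None:
        out = {
            "base_correlation": self.base_correlation.tolist(),
            "subtype_of_subject": self.subtype_of_subject,
            "effects": [{"pairs": list(e.pairs), "delta_z": e.delta_z} for e in self.effects],
        }
        Path(path).write_text(json.dumps(out, indent=1))


def make_base_correlation(n_regions: int, rank: int, seed: int) -> np.ndarray:
    """Low-rank-plus-diagonal baseline correlation matrix.

    Loadings W are (R, rank) Gaussians scaled by 1/sqrt(rank); the covariance
    W W' + I is normalised to a correlation matrix, which is symmetric
    positive definite with off-diagonal magnitudes strictly below 1.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if not 1 <= rank <= n_regions:
        raise ValueError("rank must be in [1, n_regions]")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n_regions, rank)) / np.sqrt(rank)
    cov = w @ w.T + np.eye(n_regions)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_correlation(
    matrix: np.ndarray, tol: float = 1e-8, max_iter: int = 100
) -> np.ndarray:
    """Nearest valid correlation matrix by alternating projections.

    Higham's alternating projections between the PSD cone (eigenvalue
    clipping at 0, with Dykstra correction) and the unit-diagonal set;
    convergence at Frobenius change below ``tol``, at most ``max_iter``
    iterations. A matrix that is already PSD (smallest eigenvalue above
    -1e-10) is returned unchanged. The converged matrix gets a final
    eigenvalue clip and diagonal renormalisation so the result is exactly
    PSD with a unit diagonal.
    """
    matrix = np.asarray(matrix, dtype=float)
    if np.linalg.eigvalsh(matrix)[0] >= -1e-10:
        return matrix
    y = matrix.copy()
    correction = np.zeros_like(matrix)
    converged = False
    for _ in range(max_iter):
        r = y - correction
        w, v = np.linalg.eigh(r)
        x_psd = (v * np.clip(w, 0.0, None)) @ v.T
        correction = x_psd - r
        y_new = x_psd.copy()
        np.fill_diagonal(y_new, 1.0)
        if np.linalg.norm(y_new - y, "fro") < tol * max(1.0, np.linalg.norm(y, "fro")):
            y = y_new
            converged = True
            break
        y = y_new
    if not converged and np.linalg.eigvalsh(y)[0] < -100 * tol:
        raise SimulationError(
            f"correlation projection did not converge within {max_iter} iterations"
        )
    w, v = np.linalg.eigh(y)
    a = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.diag(a))
    if np.any(d <= 0):
        raise SimulationError("correlation projection produced a zero-variance region")
    return a / np.outer(d, d)


def apply_effect_in_z(
    corr: np.ndarray, pairs, delta_z: float, pair_index: PairIndex | None = None
) -> np.ndarray:
    """Shift the listed pairs by delta_z in Fisher-z space and re-project.

    The affected entries become tanh(atanh(c) + delta_z); entries at |c|=1
    are refused (z undefined). The result is the nearest valid correlation
    matrix, which equals the direct construction whenever it is already PSD
    (in particular, delta_z=0 returns the input unchanged when valid).
    """
    corr = np.asarray(corr, dtype=float)
    pidx = pair_index or PairIndex(corr.shape[0])
    out = corr.copy()
    for k in pairs:
        i, j = pidx.to_pair(int(k))
        c = corr[i, j]
        if abs(c) >= 1.0:
            raise ValueError(f"|correlation|=1 at pair ({i},{j}): z-shift undefined")
        v = np.tanh(np.arctanh(c) + delta_z)
        out[i, j] = out[j, i] = v
    return nearest_correlation(out)


def _perturb_z(
    corr: np.ndarray, sigma: float, rng: np.random.Generator, pidx: PairIndex
) -> np.ndarray:
    """Add N(0, sigma^2) z-noise to every off-diagonal entry, re-project."""
    if sigma == 0:
        return corr
    z = np.arctanh(np.clip(pidx.condense(corr), -1 + 1e-12, 1 - 1e-12))
    z = z + rng.normal(0.0, sigma, size=z.shape)
    out = pidx.to_matrix(np.tanh(z), diagonal=1.0)
    return nearest_correlation(out)


def _correlation_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L L' = corr, tolerant of PSD-singular targets."""
    w, v = np.linalg.eigh(corr)
    return v * np.sqrt(np.clip(w, 0.0, None))


def sample_timeseries(
    corr: np.ndarray, n_timepoints: int, rng: np.random.Generator, ar1: float = 0.0
) -> np.ndarray:
    """Zero-mean Gaussian T x R series with cross-region correlation ``corr``.

    With ar1 != 0, each region is an AR(1) process driven by correlated
    innovations, x_t = ar1 * x_{t-1} + sqrt(1-ar1^2) * e_t with e_t ~
    N(0, corr) and x_0 stationary, so the stationary cross-region
    correlation still equals ``corr``.
    """
    factor = _correlation_factor(corr)
    innov = rng.standard_normal((n_timepoints, corr.shape[0])) @ factor.T
    if ar1 == 0.0:
        return innov
    out = np.empty_like(innov)
    out[0] = innov[0]
    scale = np.sqrt(1.0 - ar1 * ar1)
    for t in range(1, n_timepoints):
        out[t] = ar1 * out[t - 1] + scale * innov[t]
    return out


def simulate_cohort(config: SimConfig) -> tuple[list[ScanRecord], GroundTruth]:
    """Generate the full cohort of scans plus its ground truth.

    Deterministic given the config (including its seed). Scan ids are
    ``{dataset}_{subject}_r{replicate}``; region ids are 0..R-1.
    """
    rng = np.random.default_rng(config.seed)
    pidx = PairIndex(config.n_regions)
    base_seed = config.seed if config.base_seed is None else config.base_seed
    base = make_base_correlation(config.n_regions, config.base_structure_rank, base_seed)
    truth = GroundTruth(
        base_correlation=base,
        subtype_of_subject={},
        effects=config.effect_pairs,
    )
    region_ids = tuple(range(config.n_regions))
    scans: list[ScanRecord] = []
    n_total = config.n_subjects_nc + config.n_subjects_pd
    stratified: list[int] = []
    if config.effect_pairs and config.subtype_assignment == "stratified":
        # largest-remainder apportionment of subtypes over PD subjects
        props = np.asarray(config.subtype_proportions)
        counts = np.floor(props * config.n_subjects_pd).astype(int)
        remainder = props * config.n_subjects_pd - counts
        for k in np.argsort(-remainder)[: config.n_subjects_pd - counts.sum()]:
            counts[k] += 1
        stratified = [k for k, c in enumerate(counts) for _ in range(c)]
        stratified = [int(x) for x in rng.permutation(stratified)]
    for s in range(n_total):
        is_pd = s >= config.n_subjects_nc
        group = "PD" if is_pd else "NC"
        subject_id = f"{config.dataset_id}_{group.lower()}{s:03d}"
        subtype = -1
        target = base
        if is_pd and config.effect_pairs:
            if config.subtype_assignment == "stratified":
                subtype = stratified[s - config.n_subjects_nc]
            else:
                subtype = int(
                    rng.choice(
                        len(config.effect_pairs), p=np.asarray(config.subtype_proportions)
                    )
                )
            eff = config.effect_pairs[subtype]
            # NC - PD convention: a positive delta_z means FC *reduced* in PD
            target = apply_effect_in_z(base, eff.pairs, -eff.delta_z, pidx)
        truth.subtype_of_subject[subject_id] = subtype
        subj_corr = _perturb_z(target, config.sigma_subject, rng, pidx)
        for rep in range(1, config.n_replicates + 1):
            scan_corr = _perturb_z(subj_corr, config.sigma_scan, rng, pidx)
            scan_id = f"{subject_id}_r{rep}"
            try:
                values = sample_timeseries(
                    scan_corr, config.n_timepoints, rng, config.ar1_coefficient
                )
            except SimulationError as err:  # pragma: no cover - defensive
                raise SimulationError(f"scan {scan_id}: {err}") from err
            truth.scan_target[scan_id] = scan_corr
            scans.append(
                ScanRecord(
                    scan_id=scan_id,
                    subject_id=subject_id,
                    group=group,
                    dataset_id=config.dataset_id,
                    replicate_index=rep,
                    timeseries=ROITimeseries(
                        values=values, tr_seconds=config.tr_seconds, region_ids=region_ids
                    ),
                )
            )
    return scans, truth
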