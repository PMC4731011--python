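"""Paired mRNA/protein time-course simulators with known kinetic ground truth.

Two generators are provided:

``simulate_qss``
    Quasi-steady-state generator matched to the inference model: on the log
    scale each gene's RNA trace equals its per-interval log rate ratio
    (piecewise constant, changes only at interior grid points) plus Gaussian
    noise, and the protein trace equals the noise-free RNA trace plus the
    protein-level log rate ratio plus independent noise.  Used for
    calibration tests because the model is exactly correct for these data.

``simulate_ode``
    First-order kinetic generator deliberately mismatched to the inference
    model: it integrates dM/dt = s_R - d_R*M and dP/dt = s_P*M - d_P*P with
    piecewise-constant rates and applies multiplicative log-normal noise.
    Used for robustness tests — relaxation to the new steady state is
    gradual, so the piecewise-constant-mean assumption only holds
    approximately.

Regulatory programs follow the two archetypes seen in stress-response time
courses: a *pulse* (rate-ratio shift at 2 h that reverts at 8 h) and a
*switch* (single permanent shift at 2 h).  Unregulated genes are *null*.
All randomness flows from ``config.seed`` through a spawned
``numpy.random.SeedSequence`` tree, one independent stream per purpose
(ground truth; noise per level x replicate; spikes; missingness), so
replicates share truth but never noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_TIME_GRID,
    LOG,
    NATURAL,
    PROTEIN,
    RNA,
    ConfigurationError,
    ExpressionMatrix,
    KineticGroundTruth,
    interior_points,
    interval_labels,
)

PULSE = "pulse"
SWITCH = "switch"
NULL = "null"


@dataclass
class SimulationConfig:
    """Study-design constants for the simulators.

    Defaults mirror the experimental design the pipeline targets: an 8-point
    time course (0-30 h) in 2 biological replicates, with a minority of
    genes regulated per level by a 1.5 natural-log-unit rate-ratio shift and
    log-scale measurement noise of SD 0.2.
    """

    n_genes: int = 1000
    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    n_replicates: int = 2
    frac_regulated_rna: float = 0.1
    frac_regulated_protein: float = 0.1
    effect_size: float = 1.5
    noise_sd_rna: float = 0.2
    noise_sd_protein: float = 0.2
    #: relative weights of the pulse vs switch program among regulated genes;
    #: the null share is 1 - frac_regulated at each level
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {PULSE: 0.5, SWITCH: 0.5}
    )
    #: per-level overrides of pattern_mix (e.g. pulse-like RNA regulation
    #: with switch-like protein regulation); None falls back to pattern_mix
    pattern_mix_rna: dict[str, float] | None = None
    pattern_mix_protein: dict[str, float] | None = None
    spike_rate: float = 0.02
    spike_magnitude: float = 3.0
    missing_rate: float = 0.02
    seed: int = 0
    #: hour at which regulated programs shift, and at which pulses revert
    shift_time: float = 2.0
    revert_time: float = 8.0
    #: baseline log RNA abundance (natural log of intensity) mean/SD
    baseline_rna_mean: float = 5.0
    baseline_rna_sd: float = 1.0
    #: baseline protein:RNA log rate ratio mean/SD
    baseline_protein_mean: float = 2.0
    baseline_protein_sd: float = 1.0
    #: ODE mode only: median degradation rates (per hour) and lognormal spread
    ode_deg_rna: float = 0.35
    ode_deg_protein: float = 0.08
    ode_deg_spread: float = 0.3

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.size < 4 or not np.all(np.diff(grid) > 0):
            raise ConfigurationError("time_grid must be >= 4 strictly increasing hours")
        for name in ("frac_regulated_rna", "frac_regulated_protein", "spike_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.noise_sd_rna < 0 or self.noise_sd_protein < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        for mix in (self.pattern_mix, self.pattern_mix_rna, self.pattern_mix_protein):
            if mix is None:
                continue
            w = [mix.get(PULSE, 0.0), mix.get(SWITCH, 0.0)]
            if min(w) < 0 or sum(w) <= 0:
                raise ConfigurationError("pattern mix needs non-negative pulse/switch weights")
        if self.shift_time not in self.time_grid or self.revert_time not in self.time_grid:
            raise ConfigurationError("shift_time and revert_time must lie on the grid")
        i, j = (list(self.time_grid).index(self.shift_time),
                list(self.time_grid).index(self.revert_time))
        if not (0 < i < j < len(self.time_grid) - 1):
            raise ConfigurationError("shift/revert must be interior grid points in order")

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index([f"G{i + 1:06d}" for i in range(self.n_genes)], name="gene_id")


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """Named independent RNG streams derived from the single seed."""
    root = np.random.SeedSequence(config.seed)
    names = ["truth", "spikes", "missing"]
    for level in (RNA, PROTEIN):
        for rep in range(1, config.n_replicates + 1):
            names.append(f"noise:{level}:{rep}")
    children = root.spawn(len(names))
    return {name: np.random.default_rng(seq) for name, seq in zip(names, children)}


def _assign_patterns(
    config: SimulationConfig, frac_regulated: float, rng: np.random.Generator,
    mix: dict[str, float] | None = None,
) -> np.ndarray:
    """Pattern label per gene for one level (pulse/switch/null)."""
    mix = mix or config.pattern_mix
    n = config.n_genes
    n_reg = int(round(frac_regulated * n))
    labels = np.full(n, NULL, dtype=object)
    if n_reg == 0:
        return labels
    reg_idx = rng.choice(n, size=n_reg, replace=False)
    w = np.array([mix.get(PULSE, 0.0), mix.get(SWITCH, 0.0)])
    labels[reg_idx] = rng.choice([PULSE, SWITCH], size=n_reg, p=w / w.sum())
    return labels


def _build_theta(
    config: SimulationConfig,
    patterns: np.ndarray,
    baseline: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genes x intervals matrix of true log rate ratios.

    Interval ``i`` spans ``[t_i, t_{i+1}]``; a program shift at an interior
    grid point changes the rate ratio of the interval that starts there.
    """
    grid = np.asarray(config.time_grid, dtype=float)
    n_int = grid.size - 1
    i_shift = int(np.where(grid == config.shift_time)[0][0])
    i_revert = int(np.where(grid == config.revert_time)[0][0])
    theta = np.tile(baseline[:, None], (1, n_int))
    delta = config.effect_size * rng.choice([-1.0, 1.0], size=config.n_genes)
    pulse = patterns == PULSE
    switch = patterns == SWITCH
    theta[pulse, i_shift:i_revert] += delta[pulse, None]
    theta[switch, i_shift:] += delta[switch, None]
    return theta


def _z_from_theta(theta: np.ndarray) -> np.ndarray:
    """Change indicators at interior points: z_j = [theta_j != theta_{j-1}]."""
    return (np.abs(np.diff(theta, axis=1)) > 1e-12).astype(int)


def _point_means(theta: np.ndarray) -> np.ndarray:
    """Expected log value at each time point: point j carries the rate ratio
    of the interval starting at t_j (the last point carries the final one)."""
    return np.hstack([theta, theta[:, -1:]])


def _truth_frames(
    config: SimulationConfig, theta: dict[str, np.ndarray], patterns: dict[str, np.ndarray]
) -> KineticGroundTruth:
    grid = np.asarray(config.time_grid, dtype=float)
    cols_int = interval_labels(grid)
    cols_ip = interior_points(grid)
    genes = config.gene_ids
    return KineticGroundTruth(
        theta={lv: pd.DataFrame(theta[lv], index=genes, columns=cols_int) for lv in theta},
        z={
            lv: pd.DataFrame(_z_from_theta(theta[lv]), index=genes, columns=cols_ip)
            for lv in theta
        },
        pattern={lv: pd.Series(patterns[lv], index=genes, name="pattern") for lv in patterns},
        noise_sd={RNA: config.noise_sd_rna, PROTEIN: config.noise_sd_protein},
    )


def simulate_qss(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], list[ExpressionMatrix], KineticGroundTruth]:
    """Quasi-steady-state simulation.

    Returns (rna matrices per replicate, protein matrices per replicate,
    ground truth).  Matrices are on the natural scale, ready for the
    preprocessing entry point; truth is shared across replicates and only
    the noise differs.  Deterministic given ``config.seed``.
    """
    rng = _streams(config)
    grid = np.asarray(config.time_grid, dtype=float)
    genes = config.gene_ids

    pat_r = _assign_patterns(config, config.frac_regulated_rna, rng["truth"], config.pattern_mix_rna)
    pat_p = _assign_patterns(config, config.frac_regulated_protein, rng["truth"], config.pattern_mix_protein)
    base_r = rng["truth"].normal(config.baseline_rna_mean, config.baseline_rna_sd, config.n_genes)
    base_p = rng["truth"].normal(
        config.baseline_protein_mean, config.baseline_protein_sd, config.n_genes
    )
    theta_r = _build_theta(config, pat_r, base_r, rng["truth"])
    theta_p = _build_theta(config, pat_p, base_p, rng["truth"])

    log_rna_clean = _point_means(theta_r)
    log_protein_clean = log_rna_clean + _point_means(theta_p)

    rna_mats, protein_mats = [], []
    for rep in range(1, config.n_replicates + 1):
        eps_r = rng[f"noise:{RNA}:{rep}"].normal(0, config.noise_sd_rna, log_rna_clean.shape)
        eps_p = rng[f"noise:{PROTEIN}:{rep}"].normal(
            0, config.noise_sd_protein, log_protein_clean.shape
        )
        rna_mats.append(
            ExpressionMatrix(
                pd.DataFrame(np.exp(log_rna_clean + eps_r), index=genes, columns=grid),
                level=RNA, scale=NATURAL, replicate=rep,
            )
        )
        protein_mats.append(
            ExpressionMatrix(
                pd.DataFrame(np.exp(log_protein_clean + eps_p), index=genes, columns=grid),
                level=PROTEIN, scale=NATURAL, replicate=rep,
            )
        )
    truth = _truth_frames(config, {RNA: theta_r, PROTEIN: theta_p}, {RNA: pat_r, PROTEIN: pat_p})
    return rna_mats, protein_mats, truth


# ---------------------------------------------------------------------------
# ODE generator


def _ode_segment_M(m0: float, s: float, d: float, tau: np.ndarray) -> np.ndarray:
    """Exact mRNA trajectory over one constant-rate segment."""
    mss = s / d
    return mss + (m0 - mss) * np.exp(-d * tau)


def _ode_segment_P(
    p0: float, m0: float, s_r: float, d_r: float, s_p: float, d_p: float, tau: np.ndarray
) -> np.ndarray:
    """Exact protein trajectory over one constant-rate segment.

    With M(tau) = Mss + A*exp(-d_r*tau), the linear protein ODE integrates to
    Pss + B*exp(-d_p*tau) + C*exp(-d_r*tau); the degenerate d_p == d_r case
    picks up a tau*exp(-d*tau) term instead.
    """
    mss = s_r / d_r
    a = m0 - mss
    pss = s_p * mss / d_p
    if abs(d_p - d_r) < 1e-9:
        # resonant case: particular solution s_p*A*tau*exp(-d*tau)
        return pss + (p0 - pss) * np.exp(-d_p * tau) + s_p * a * tau * np.exp(-d_p * tau)
    c = s_p * a / (d_p - d_r)
    b = p0 - pss - c
    return pss + b * np.exp(-d_p * tau) + c * np.exp(-d_r * tau)


def simulate_ode(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], list[ExpressionMatrix], KineticGroundTruth]:
    """First-order kinetic simulation with piecewise-constant rates.

    Rate-ratio programs are realised by scaling the synthesis rates by
    exp(effect) over the program window; degradation rates stay fixed, so
    the true log rate ratio per interval is log(s/d) with the same pulse /
    switch structure as the QSS generator.  Trajectories start at the
    pre-treatment steady state and are integrated exactly segment by
    segment (linear ODEs).  Multiplicative log-normal noise is applied per
    replicate.
    """
    rng = _streams(config)
    grid = np.asarray(config.time_grid, dtype=float)
    genes = config.gene_ids
    n = config.n_genes

    pat_r = _assign_patterns(config, config.frac_regulated_rna, rng["truth"], config.pattern_mix_rna)
    pat_p = _assign_patterns(config, config.frac_regulated_protein, rng["truth"], config.pattern_mix_protein)
    base_r = rng["truth"].normal(config.baseline_rna_mean, config.baseline_rna_sd, n)
    base_p = rng["truth"].normal(config.baseline_protein_mean, config.baseline_protein_sd, n)

    d_r = config.ode_deg_rna * np.exp(rng["truth"].normal(0, config.ode_deg_spread, n))
    d_p = config.ode_deg_protein * np.exp(rng["truth"].normal(0, config.ode_deg_spread, n))
    if np.any(d_r <= 0) or np.any(d_p <= 0):
        raise ConfigurationError("degradation rates must be positive (no steady state)")
    # baseline synthesis rates chosen so log(s/d) equals the baseline theta
    theta_r = _build_theta(config, pat_r, base_r, rng["truth"])
    theta_p = _build_theta(config, pat_p, base_p, rng["truth"])
    n_int = grid.size - 1
    s_r = np.exp(theta_r) * d_r[:, None]  # genes x intervals
    s_p = np.exp(theta_p) * d_p[:, None]

    # integrate gene by gene, segment by segment, sampling grid points exactly
    M = np.empty((n, grid.size))
    P = np.empty((n, grid.size))
    for g in range(n):
        m = float(np.exp(theta_r[g, 0]))          # steady state s_R/d_R at baseline
        p = float(m * np.exp(theta_p[g, 0]))      # steady state (s_P/d_P)*M
        M[g, 0], P[g, 0] = m, p
        for i in range(n_int):
            tau = np.array([grid[i + 1] - grid[i]])
            m_next = _ode_segment_M(m, s_r[g, i], d_r[g], tau)[0]
            p_next = _ode_segment_P(p, m, s_r[g, i], d_r[g], s_p[g, i], d_p[g], tau)[0]
            m, p = m_next, p_next
            M[g, i + 1], P[g, i + 1] = m, p

    rna_mats, protein_mats = [], []
    for rep in range(1, config.n_replicates + 1):
        eps_r = rng[f"noise:{RNA}:{rep}"].normal(0, config.noise_sd_rna, M.shape)
        eps_p = rng[f"noise:{PROTEIN}:{rep}"].normal(0, config.noise_sd_protein, P.shape)
        rna_mats.append(
            ExpressionMatrix(
                pd.DataFrame(M * np.exp(eps_r), index=genes, columns=grid),
                level=RNA, scale=NATURAL, replicate=rep,
            )
        )
        protein_mats.append(
            ExpressionMatrix(
                pd.DataFrame(P * np.exp(eps_p), index=genes, columns=grid),
                level=PROTEIN, scale=NATURAL, replicate=rep,
            )
        )
    truth = _truth_frames(config, {RNA: theta_r, PROTEIN: theta_p}, {RNA: pat_r, PROTEIN: pat_p})
    cols = interval_labels(grid)
    truth.rates = {
        RNA: {
            "synthesis": pd.DataFrame(s_r, index=genes, columns=cols),
            "degradation": pd.DataFrame(np.tile(d_r[:, None], (1, n_int)), index=genes, columns=cols),
        },
        PROTEIN: {
            "synthesis": pd.DataFrame(s_p, index=genes, columns=cols),
            "degradation": pd.DataFrame(np.tile(d_p[:, None], (1, n_int)), index=genes, columns=cols),
        },
    }
    return rna_mats, protein_mats, truth


# ---------------------------------------------------------------------------
# measurement artifacts


def inject_spikes(
    matrix: ExpressionMatrix,
    spike_rate: float,
    spike_magnitude: float,
    seed: int,
) -> tuple[ExpressionMatrix, list[str]]:
    """Displace one randomly chosen time point per selected gene.

    ``round(spike_rate * n_genes)`` genes are selected; each gets a single
    cell displaced by +/- ``spike_magnitude`` on the log scale (a
    multiplicative factor exp(+/-magnitude) on the natural scale).
    Returns the modified matrix and the affected gene ids.
    """
    if not 0.0 <= spike_rate <= 1.0:
        raise ConfigurationError(f"spike_rate={spike_rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    n_genes, n_time = values.shape
    n_spiked = int(round(spike_rate * n_genes))
    if n_spiked == 0:
        return matrix.copy_with(values), []
    rows = rng.choice(n_genes, size=n_spiked, replace=False)
    cols = rng.integers(0, n_time, size=n_spiked)
    signs = rng.choice([-1.0, 1.0], size=n_spiked)
    arr = values.to_numpy(copy=True)
    if matrix.scale == LOG:
        arr[rows, cols] += signs * spike_magnitude
    else:
        arr[rows, cols] *= np.exp(signs * spike_magnitude)
    values.iloc[:, :] = arr
    return matrix.copy_with(values), list(values.index[np.sort(rows)])


def inject_missing(matrix: ExpressionMatrix, missing_rate: float, seed: int) -> ExpressionMatrix:
    """Blank ``round(rate * n_cells)`` cells uniformly at random (NaN)."""
    if not 0.0 <= missing_rate < 1.0:
        raise ConfigurationError(f"missing_rate={missing_rate} outside [0, 1)")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    n_cells = values.size
    n_missing = int(round(missing_rate * n_cells))
    if n_missing == 0:
        return matrix.copy_with(values)
    flat = rng.choice(n_cells, size=n_missing, replace=False)
    arr = values.to_numpy(copy=True).astype(float)
    arr[np.unravel_index(flat, arr.shape)] = np.nan
    values.iloc[:, :] = arr
    return matrix.copy_with(values)


def simulate_dataset(
    config: SimulationConfig, mode: str = "qss"
) -> tuple[list[ExpressionMatrix], list[ExpressionMatrix], KineticGroundTruth, list[str]]:
    """Full dataset: simulate, then apply spikes and missingness per config.

    Artifact seeds derive from the config seed, so the whole dataset is
    reproducible.  Returns the matrices, the truth, and the union of spiked
    gene ids across all matrices.
    """
    sim = {"qss": simulate_qss, "ode": simulate_ode}.get(mode)
    if sim is None:
        raise ConfigurationError(f"unknown simulation mode {mode!r}")
    rna, protein, truth = sim(config)
    spiked: set[str] = set()
    out_r, out_p = [], []
    sub = np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(2 * len(rna) * 2)
    k = 0
    for mats, out in ((rna, out_r), (protein, out_p)):
        for m in mats:
            m2, genes = inject_spikes(m, config.spike_rate, config.spike_magnitude, int(sub[k] % 2**31))
            m3 = inject_missing(m2, config.missing_rate, int(sub[k + 1] % 2**31))
            spiked.update(genes)
            out.append(m3)
            k += 2
    return out_r, out_p, truth, sorted(spiked)
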