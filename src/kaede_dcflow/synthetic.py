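"""Synthetic Kaede photoconversion data.

Emulates the experimental design of photoconvertible-reporter tumour studies:
cells enter the tumour as conventional DCs (cDC), mature through an activated
CCR7+ DC state (DC1) into one of two terminal activated states (DC2, DC3),
and egress to the draining lymph node (dLN) at state-dependent rates.  A
single photoconversion event at ``t_conv`` turns every tumour-resident cell
"red"; cells entering afterwards are "green", so the red/green split encodes
tumour dwell time.

The module provides

* a per-cell continuous-time Markov chain simulator (:func:`simulate_dwell`),
* a matrix-exponential occupancy oracle (:func:`expected_red_fraction`) for
  the same chain, used to validate simulated label compositions,
* negative-binomial expression sampling with planted gene programs
  (:class:`GeneProgram`, :func:`sample_expression`),
* spatial spot lattices with correlated-score hotspots, centroid fields with
  controllable class coupling, and survival cohorts whose hazard depends on a
  latent signature abundance.

All functions are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.sparse import csr_matrix

STATES = ("S0_cDC", "S1_DC1", "S2_DC2", "S3_DC3")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class DwellModelParams:
    """Rates (1/hour) and timing (hours) of the tumour dwell-time chain.

    The chain is cDC -> DC1 -> {DC2, DC3} with egress to the dLN at rate
    ``e1`` from DC1 and ``e23`` from DC2/DC3.  Cells enter the tumour as cDC
    following a Poisson process of intensity ``entry_rate``.  Under treatment
    the DC1 -> DC2 branch probability k12/(k12+k13) is multiplied by
    ``treatment_split_multiplier`` (clipped to [0, 1]); the total DC1 exit
    rate is unchanged.
    """

    entry_rate: float = 30.0
    k01: float = 0.08
    k12: float = 0.05
    k13: float = 0.05
    e1: float = 0.02
    e23: float = 0.005
    t_conv: float = 120.0
    harvest_offsets: tuple = (5.0, 24.0, 48.0, 72.0)
    treatment_split_multiplier: float = 1.6
    mislabel_rate: float = 0.0

    def __post_init__(self):
        for name in ("entry_rate", "k01", "k12", "k13", "e1", "e23", "t_conv"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate/time {name!r} must be >= 0")
        if self.treatment_split_multiplier <= 0:
            raise ValueError("treatment_split_multiplier must be > 0")
        if not 0.0 <= self.mislabel_rate <= 1.0:
            raise ValueError("mislabel_rate must be in [0, 1]")

    def branch_split(self, treated: bool) -> tuple[float, float]:
        """Effective (k12, k13) given the treatment flag."""
        total = self.k12 + self.k13
        if total == 0:
            return 0.0, 0.0
        p12 = self.k12 / total
        if treated:
            p12 = min(1.0, p12 * self.treatment_split_multiplier)
        return p12 * total, (1.0 - p12) * total

    def generator(self, treated: bool = False) -> np.ndarray:
        """4x4 CTMC generator over tumour states; egress appears as loss."""
        k12, k13 = self.branch_split(treated)
        q = np.zeros((4, 4))
        q[0, 0] = -self.k01
        q[0, 1] = self.k01
        q[1, 1] = -(k12 + k13 + self.e1)
        q[1, 2] = k12
        q[1, 3] = k13
        q[2, 2] = -self.e23
        q[3, 3] = -self.e23
        return q


def _occupancy_integral(q: np.ndarray, t: float) -> np.ndarray:
    """Return ``int_0^t e0' expm(Q u) du`` (expected occupancy of Poisson
    entrants over a window of length t, per unit entry rate)."""
    aug = np.zeros((8, 8))
    aug[:4, :4] = q
    aug[:4, 4:] = np.eye(4)
    block = expm(aug * t)[:4, 4:]
    return block[0]  # entrants start in S0


def expected_red_fraction(
    params: DwellModelParams, state: str, offset: float, treated: bool = False
) -> float:
    """Closed-form expected Kaede-red fraction of tumour state at ``offset``
    hours after photoconversion.

    Red occupancy evolves the pre-conversion occupancy (Poisson entries on
    [0, t_conv]) through the transition-rate matrix for ``offset`` hours;
    green occupancy integrates post-conversion entries through the same
    matrix.  The per-state fraction is red / (red + green).
    """
    if state not in STATE_INDEX:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    q = params.generator(treated)
    red_at_conv = params.entry_rate * _occupancy_integral(q, params.t_conv)
    red = red_at_conv @ expm(q * offset)
    green = params.entry_rate * _occupancy_integral(q, offset)
    i = STATE_INDEX[state]
    denom = red[i] + green[i]
    if denom == 0:
        return 1.0
    return float(red[i] / denom)


def simulate_dwell(
    params: DwellModelParams,
    horizon: float | None = None,
    seed: int = 0,
    treated: bool = False,
    entry_stop: float | None = None,
) -> pd.DataFrame:
    """Simulate independent cell trajectories through the dwell-time chain.

    One independent cohort is simulated per harvest offset (each offset is a
    separate animal in the emulated design).  Returns a DataFrame with one
    row per cell and columns ``cell_id, harvest_offset_h, entry_time, state,
    compartment, kaede, egress_time, treatment``.

    Parameters
    ----------
    horizon
        Ignored unless it exceeds the largest harvest time; present so a
        caller can assert coverage (must be >= t_conv + max offset).
    entry_stop
        If given, Poisson entries stop at this time (e.g. ``t_conv`` to
        verify that without post-conversion entrants every cell is red).
    """
    t_max = params.t_conv + max(params.harvest_offsets)
    if horizon is None:
        horizon = t_max
    if horizon < t_max:
        raise ValueError("horizon must cover t_conv + max(harvest_offsets)")
    rng = np.random.default_rng(seed)
    frames = []
    for offset in params.harvest_offsets:
        frames.append(
            _simulate_one_harvest(params, float(offset), rng, treated, entry_stop)
        )
    out = pd.concat(frames, ignore_index=True)
    out["cell_id"] = [f"cell{idx:07d}" for idx in range(len(out))]
    return out


def _simulate_one_harvest(params, offset, rng, treated, entry_stop):
    t_harvest = params.t_conv + offset
    t_entry_max = t_harvest if entry_stop is None else min(entry_stop, t_harvest)
    n = rng.poisson(params.entry_rate * t_entry_max)
    entry = np.sort(rng.uniform(0.0, t_entry_max, size=n))

    def exp_draw(rate, size):
        if rate == 0:
            return np.full(size, np.inf)
        return rng.exponential(1.0 / rate, size=size)

    k12, k13 = params.branch_split(treated)
    d0 = exp_draw(params.k01, n)  # dwell in S0
    r1 = k12 + k13 + params.e1
    d1 = exp_draw(r1, n)  # dwell in S1
    # competing outcome from S1
    if r1 > 0:
        u = rng.random(n)
        p = np.array([k12, k13, params.e1]) / r1
        outcome = np.searchsorted(np.cumsum(p), u)  # 0->S2, 1->S3, 2->egress
    else:
        outcome = np.full(n, -1)
    d23 = exp_draw(params.e23, n)  # dwell in S2/S3 before egress

    t_s1 = entry + d0
    t_exit_s1 = t_s1 + d1
    t_egress = np.where(
        outcome == 2, t_exit_s1, np.where(outcome >= 0, t_exit_s1 + d23, np.inf)
    )
    # egress only materialises if the cell actually left S1 first
    t_egress = np.where(t_exit_s1 <= t_harvest, t_egress, np.inf)
    # a cell still in S0 or S1 at harvest has not egressed
    egressed = t_egress <= t_harvest

    state = np.full(n, 0)
    in_s1 = (t_s1 <= t_harvest) & (t_exit_s1 > t_harvest)
    state[in_s1] = 1
    left_s1 = t_exit_s1 <= t_harvest
    state[left_s1 & (outcome == 0)] = 2
    state[left_s1 & (outcome == 1)] = 3
    state[left_s1 & (outcome == 2)] = 1  # egressed directly from S1

    in_tumour_at_conv = (entry <= params.t_conv) & (t_egress > params.t_conv)
    kaede = np.where(in_tumour_at_conv, "red", "green")
    if params.mislabel_rate > 0:
        flip = rng.random(n) < params.mislabel_rate
        kaede = np.where(
            flip, np.where(kaede == "red", "green", "red"), kaede
        )

    return pd.DataFrame(
        {
            "harvest_offset_h": offset,
            "entry_time": entry,
            "state": np.array(STATES)[state],
            "compartment": np.where(egressed, "dLN", "tumour"),
            "kaede": kaede,
            "egress_time": np.where(egressed, t_egress, np.nan),
            "treatment": "aPDL1" if treated else "isotype",
        }
    )


# ---------------------------------------------------------------------------
# expression programs
# ---------------------------------------------------------------------------

@dataclass
class GeneProgram:
    """State-specific negative-binomial gene programs with planted sets.

    The mean model for gene g in cell i is
    ``mu_gi = L_i * p_gi`` with ``p_gi`` proportional to
    ``baseline_g * 2**(theta[g, state_i] + treatment_shift_g * treated_i)``
    normalised per cell, so counts sum to the cell's library size L_i in
    expectation.  Variance is ``mu + phi * mu**2`` (NB2).
    """

    baseline: np.ndarray
    theta: np.ndarray  # (genes, 4) log2 effects per state
    treatment_shift: np.ndarray
    dispersion: np.ndarray
    gene_names: list
    signatures: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.dispersion <= 0):
            raise ValueError("dispersion phi must be > 0 for every gene")
        if self.theta.shape != (len(self.baseline), len(STATES)):
            raise ValueError("theta must be (n_genes, n_states)")

    @classmethod
    def default(cls, n_genes: int = 2000, set_size: int = 40, seed: int = 0):
        """Planted programs: an activation set up in every activated state
        (strongest in DC2), an antigen-presentation set decreasing
        DC1 -> DC3, an interferon-response set shifted up under treatment,
        and a DC2-only marker set (log2 effect 2)."""
        rng = np.random.default_rng(seed)
        if n_genes < 4 * set_size:
            raise ValueError("n_genes too small for the planted sets")
        baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
        theta = np.zeros((n_genes, 4))
        shift = np.zeros(n_genes)
        names = []
        sig = {}
        blocks = [
            ("activation", "ACT", np.array([0.0, 1.0, 2.0, 1.0]), 0.0),
            ("antigen_presentation", "MHC", np.array([1.5, 1.5, 0.75, 0.0]), 0.0),
            ("ifn_response", "IFN", np.array([0.0, 0.0, 0.0, 0.0]), 1.5),
            ("dc2_marker", "DC2M", np.array([0.0, 0.0, 2.0, 0.0]), 0.0),
        ]
        for b, (set_name, prefix, th, sh) in enumerate(blocks):
            lo = b * set_size
            theta[lo : lo + set_size] = th
            shift[lo : lo + set_size] = sh
            block_names = [f"{prefix}{j:04d}" for j in range(set_size)]
            names.extend(block_names)
            sig[set_name] = block_names
        names.extend(f"NULL{j:05d}" for j in range(n_genes - 4 * set_size))
        dispersion = rng.uniform(0.1, 0.4, size=n_genes)
        return cls(baseline, theta, shift, dispersion, names, sig)


def sample_expression(
    cells: pd.DataFrame,
    program: GeneProgram,
    library_median: float = 5000.0,
    library_sigma: float = 0.3,
    seed: int = 0,
) -> ad.AnnData:
    """Draw NB counts for every cell given its state and treatment.

    Library sizes are log-normal with the given median.  Returns an AnnData
    (cells x genes, integer counts in ``.X``) carrying the cell metadata in
    ``.obs`` plus a simulated ``mito_fraction`` column.
    """
    missing = set(cells["state"]) - set(STATES)
    if missing:
        raise ValueError(f"program does not cover states {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = len(cells)
    state_idx = cells["state"].map(STATE_INDEX).to_numpy()
    treated = (cells["treatment"] == "aPDL1").to_numpy()
    lib = rng.lognormal(mean=np.log(library_median), sigma=library_sigma, size=n)

    log2_mu = (
        np.log2(program.baseline)[None, :]
        + program.theta.T[state_idx]
        + np.outer(treated.astype(float), program.treatment_shift)
    )
    p = np.exp2(log2_mu)
    p /= p.sum(axis=1, keepdims=True)
    mu = lib[:, None] * p
    phi = program.dispersion[None, :]
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    counts = rng.poisson(lam)

    obs = cells.reset_index(drop=True).copy()
    obs.index = obs["cell_id"].astype(str)
    obs["mito_fraction"] = rng.beta(2.0, 40.0, size=n)
    obs["tissue"] = np.where(obs["compartment"] == "tumour", "tumour", "dLN")
    adata = ad.AnnData(
        X=csr_matrix(counts), obs=obs, var=pd.DataFrame(index=program.gene_names)
    )
    adata.uns["planted_signatures"] = {k: list(v) for k, v in program.signatures.items()}
    return adata


# ---------------------------------------------------------------------------
# spatial fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HotspotSpec:
    """Circular region in which scoreX and scoreY share a latent factor."""

    center_x: float
    center_y: float
    radius: float
    rho: float = 0.9

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("hotspot rho must lie in [-1, 1]")


def simulate_spots(
    n_x: int = 30,
    n_y: int = 30,
    spacing: float = 100.0,
    hotspots: tuple = (HotspotSpec(1200.0, 1200.0, 420.0, 0.9),),
    score_mean: float = 1.0,
    score_sd: float = 0.3,
    zero_inflation: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Regular spot lattice with correlated-score hotspots.

    Inside a hotspot the two scores share a latent standard-normal factor
    with correlation ``rho``; outside they are independent.  With
    ``zero_inflation`` > 0 a matching fraction of entries is set to exactly
    zero to exercise downstream detection filters.
    """
    if n_x < 2 or n_y < 2:
        raise ValueError("grid dimensions must be >= 2")
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(n_x) * spacing, np.arange(n_y) * spacing)
    x = xs.ravel().astype(float)
    y = ys.ravel().astype(float)
    n = x.size
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    in_hot = np.zeros(n, dtype=bool)
    for h in hotspots:
        mask = (x - h.center_x) ** 2 + (y - h.center_y) ** 2 <= h.radius**2
        z = rng.standard_normal(n)
        a = np.where(mask, z, a)
        b = np.where(mask, h.rho * z + np.sqrt(1 - h.rho**2) * rng.standard_normal(n), b)
        in_hot |= mask
    score_x = score_mean + score_sd * a
    score_y = score_mean + score_sd * b
    if zero_inflation > 0:
        score_x = np.where(rng.random(n) < zero_inflation, 0.0, score_x)
        score_y = np.where(rng.random(n) < zero_inflation, 0.0, score_y)
    return pd.DataFrame(
        {
            "spot_id": [f"spot{idx:05d}" for idx in range(n)],
            "x": x,
            "y": y,
            "scoreX": score_x,
            "scoreY": score_y,
            "in_hotspot": in_hot,
        }
    )


def simulate_centroids(
    n_per_class: dict | None = None,
    field: tuple = (2000.0, 2000.0),
    coupling: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Segmented-cell centroid field with two classes.

    Class A is uniform over the field.  Class B is either independent uniform
    (``coupling=None``) or class-A positions plus isotropic Gaussian jitter
    of scale ``coupling`` (microns), clipped to the field.
    """
    if n_per_class is None:
        n_per_class = {"A": 500, "B": 500}
    w, h = field
    if w <= 0 or h <= 0:
        raise ValueError("field dimensions must be > 0")
    if coupling is not None and coupling < 0:
        raise ValueError("jitter sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n_a = int(n_per_class.get("A", 0))
    n_b = int(n_per_class.get("B", 0))
    ax = rng.uniform(0, w, n_a)
    ay = rng.uniform(0, h, n_a)
    if coupling is None:
        bx = rng.uniform(0, w, n_b)
        by = rng.uniform(0, h, n_b)
    else:
        if n_b > n_a:
            raise ValueError("coupled mode requires n_B <= n_A")
        bx = np.clip(ax[:n_b] + rng.normal(0, coupling, n_b), 0, w)
        by = np.clip(ay[:n_b] + rng.normal(0, coupling, n_b), 0, h)
    return pd.DataFrame(
        {
            "x": np.concatenate([ax, bx]),
            "y": np.concatenate([ay, by]),
            "cell_class": ["A"] * n_a + ["B"] * n_b,
        }
    )


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n_samples: int = 200,
    signature_genes: tuple = tuple(f"SIG{j:03d}" for j in range(20)),
    n_background_genes: int = 180,
    hazard_coef: float = -1.0,
    baseline_hazard: float = 1.0 / 40.0,
    censor_rate: float = 1.0 / 120.0,
    signature_loading: float = 0.8,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Bulk cohort whose hazard depends on a latent signature abundance.

    Each sample carries a latent abundance ``z ~ N(0, 1)``; signature genes'
    (tpm-like, log-normal) expression increases with z at ``signature_loading``
    per unit z on the log scale.  Survival time is exponential with hazard
    ``baseline_hazard * exp(hazard_coef * z)`` (months); censoring is an
    independent exponential at ``censor_rate``.

    Returns ``(expr, time, event, z)`` with expr a samples x genes DataFrame.
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_samples)
    genes = list(signature_genes) + [f"BG{j:04d}" for j in range(n_background_genes)]
    base = rng.normal(2.0, 1.0, size=len(genes))
    loading = np.zeros(len(genes))
    loading[: len(signature_genes)] = signature_loading
    log_expr = (
        base[None, :]
        + np.outer(z, loading)
        + rng.normal(0.0, noise_sd, size=(n_samples, len(genes)))
    )
    expr = pd.DataFrame(
        np.exp(log_expr),
        index=[f"sample{j:04d}" for j in range(n_samples)],
        columns=genes,
    )
    hazard = baseline_hazard * np.exp(hazard_coef * z)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return expr, time, event, z
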