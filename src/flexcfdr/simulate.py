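"""Synthetic GWAS studies over AR(1) LD blocks with auxiliary covariates.

The genome is a set of independent LD blocks; within a block the Z-score
correlation between SNPs i and j is rho^|i-j| (an AR(1) stand-in for
haplotype LD), so r^2 has the closed form rho^(2|i-j|). Causal variants get
log-odds-ratio effects from the fine-mapping prior N(0, 0.2^2); expected
Z-scores propagate through LD as Sigma * gamma and the observed Z-scores are
multivariate normal around that mean with covariance Sigma.

Auxiliary covariates come in five flavours:

  A  iid Uniform(0, 1) (null p-values, independent of the study);
  B  p-values of a second simulated GWAS sharing causal variants in exactly
     a fixed number of LD blocks (a genetically related trait);
  C  iid bimodal mixture 0.5 N(-2, 0.5^2) + 0.5 N(3, 2^2), independent;
  D  mixture normals whose component weights differ between "functional"
     SNPs (causal variants plus a 10 kb window) and the rest, with
     (mu1, mu2, w) varying across covariate realisations;
  E  functional SNPs ~ N(-2, 0.5^2), others ~ N(3, 2^2), the same
     distribution in every realisation (repeatedly measuring one mark).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LdLayout",
    "SimScenario",
    "SimulatedStudy",
    "TruthSets",
    "build_ld_layout",
    "simulate_gwas",
    "simulate_aux",
    "define_functional_snps",
    "truth_sets",
    "prune_independent_subset",
]

# (mu1, mu2, w) grids for scenario D
_MU1_GRID = (2.5, 3.0, 4.0)
_MU2_GRID = (-1.5, -2.0, -3.0)
_W_GRID = (0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass(frozen=True)
class LdLayout:
    """Block-diagonal AR(1) LD structure with evenly spaced positions."""

    n_blocks: int
    snps_per_block: int
    rho: float
    bp_spacing: int
    positions: np.ndarray = field(repr=False)

    @property
    def m(self) -> int:
        return self.n_blocks * self.snps_per_block

    def block_of(self, i) -> np.ndarray:
        return np.asarray(i) // self.snps_per_block

    def r2(self, i: int, j: int) -> float:
        """Closed-form r^2 between SNPs i and j (0 across blocks)."""
        if self.block_of(i) != self.block_of(j):
            return 0.0
        return float(self.rho ** (2 * abs(int(i) - int(j))))


def build_ld_layout(
    n_blocks: int = 24,
    snps_per_block: int = 420,
    rho: float = 0.9,
    bp_spacing: int = 400,
) -> LdLayout:
    if n_blocks < 1 or snps_per_block < 1 or bp_spacing < 1:
        raise ValueError("layout parameters must be positive")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    # blocks separated by a 100 kb gap so functional windows never span blocks
    block_span = snps_per_block * bp_spacing
    starts = np.arange(n_blocks) * (block_span + 100_000)
    offsets = np.arange(snps_per_block) * bp_spacing
    positions = (starts[:, None] + offsets[None, :]).ravel()
    return LdLayout(n_blocks, snps_per_block, rho, bp_spacing, positions)


@dataclass
class SimScenario:
    """Study conditions for one simulation scenario."""

    scenario: str = "A"
    n_causal_choices: tuple = (2, 3, 4)
    effect_sd: float = 0.2
    # expected |Z| at a causal SNP per unit log-OR: about 1/se(log OR) for a
    # 5,000-case/5,000-control study at a representative MAF of 0.2
    ncp_scale: float = 25.0
    shared_blocks: int = 4
    functional_window_bp: int = 10_000
    n_covariate_realisations: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in "ABCDE":
            raise ValueError(f"unknown scenario {self.scenario!r}")


@dataclass
class TruthSets:
    """Truth labels from closed-form r^2 with the causal variants."""

    associated: np.ndarray
    not_associated: np.ndarray


@dataclass
class SimulatedStudy:
    z: np.ndarray
    p: np.ndarray
    causal_idx: np.ndarray
    beta: np.ndarray
    layout: LdLayout
    truth: TruthSets
    seed: int
    q_realisations: list = field(default_factory=list)


def _draw_causals(layout: LdLayout, choices, rng, avoid=None):
    """Causal indices per block: count drawn from ``choices``, positions
    uniform without replacement, optionally avoiding a given index set."""
    avoid = set() if avoid is None else set(int(a) for a in avoid)
    causal = []
    for b in range(layout.n_blocks):
        k = int(rng.choice(choices))
        base = b * layout.snps_per_block
        pool = [base + i for i in range(layout.snps_per_block) if base + i not in avoid]
        if k > 0:
            causal.extend(rng.choice(pool, size=k, replace=False))
    return np.sort(np.asarray(causal, dtype=int))


def _ar1_noise(layout: LdLayout, rng) -> np.ndarray:
    """Zero-mean MVN draw with per-block AR(1) correlation rho^|i-j|."""
    eta = rng.standard_normal((layout.n_blocks, layout.snps_per_block))
    z = np.empty_like(eta)
    z[:, 0] = eta[:, 0]
    c = np.sqrt(1.0 - layout.rho**2)
    for i in range(1, layout.snps_per_block):
        z[:, i] = layout.rho * z[:, i - 1] + c * eta[:, i]
    return z.ravel()


def _expected_z(layout: LdLayout, causal: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """LD-propagated mean vector Sigma gamma (gamma nonzero at causals)."""
    mu = np.zeros(layout.m)
    within = np.arange(layout.snps_per_block)
    for c, g in zip(causal, gamma):
        b = c // layout.snps_per_block
        base = b * layout.snps_per_block
        mu[base : base + layout.snps_per_block] += g * layout.rho ** np.abs(
            within - (c - base)
        )
    return mu


def simulate_gwas(
    layout: LdLayout, scenario: SimScenario, seed: int | None = None
) -> SimulatedStudy:
    """Simulate one GWAS: Z ~ MVN(Sigma gamma, Sigma), p = 2(1 - Phi(|Z|))."""
    if layout.rho >= 1:
        raise ValueError("singular LD matrix: rho must be below 1")
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    causal = _draw_causals(layout, scenario.n_causal_choices, rng)
    beta = rng.normal(0.0, scenario.effect_sd, size=causal.size)
    gamma = scenario.ncp_scale * beta
    z = _expected_z(layout, causal, gamma) + _ar1_noise(layout, rng)
    p = 2.0 * stats.norm.sf(np.abs(z))
    study = SimulatedStudy(
        z=z,
        p=p,
        causal_idx=causal,
        beta=beta,
        layout=layout,
        truth=truth_sets_for(layout, causal),
        seed=int(seed),
    )
    return study


def define_functional_snps(study: SimulatedStudy, window_bp: int | None = None) -> np.ndarray:
    """Functional SNPs: causal variants plus everything within ``window_bp``."""
    window = 10_000 if window_bp is None else int(window_bp)
    pos = study.layout.positions
    functional = np.zeros(pos.size, dtype=bool)
    for c in study.causal_idx:
        functional |= np.abs(pos - pos[c]) <= window
    return np.nonzero(functional)[0]


def truth_sets_for(layout: LdLayout, causal: np.ndarray) -> TruthSets:
    """Associated: max r^2 with a causal >= 0.8; not-associated: <= 0.01."""
    if causal.size == 0:
        return TruthSets(
            associated=np.array([], dtype=int),
            not_associated=np.arange(layout.m),
        )
    idx = np.arange(layout.m)
    max_r2 = np.zeros(layout.m)
    for c in causal:
        same_block = layout.block_of(idx) == layout.block_of(c)
        r2 = np.where(same_block, layout.rho ** (2.0 * np.abs(idx - c)), 0.0)
        np.maximum(max_r2, r2, out=max_r2)
    return TruthSets(
        associated=np.nonzero(max_r2 >= 0.8)[0],
        not_associated=np.nonzero(max_r2 <= 0.01)[0],
    )


def truth_sets(study: SimulatedStudy) -> TruthSets:
    return truth_sets_for(study.layout, study.causal_idx)


def prune_independent_subset(layout: LdLayout, r2_threshold: float = 0.1) -> np.ndarray:
    """Greedy left-to-right pruning: keep a SNP iff r^2 with every kept SNP
    is below the threshold (a stand-in for LDAK/PLINK independent subsets)."""
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must lie in (0, 1]")
    keep = np.zeros(layout.m, dtype=bool)
    if layout.rho == 0 or r2_threshold == 1:
        keep[:] = True
        return keep
    # within a block only the nearest kept SNP matters under AR(1)
    step = 1
    while layout.rho ** (2 * step) >= r2_threshold:
        step += 1
    for b in range(layout.n_blocks):
        base = b * layout.snps_per_block
        keep[base : base + layout.snps_per_block : step] = True
    return keep


def _d_params_for_study(study: SimulatedStudy, n_realisations: int):
    """Scenario D (mu1, mu2, w) per realisation: uniform draw without
    replacement from the Cartesian grid, fixed by the study seed."""
    grid = [
        (m1, m2, w) for m1 in _MU1_GRID for m2 in _MU2_GRID for w in _W_GRID
    ]
    rng = np.random.default_rng((study.seed, 0xD))
    order = rng.permutation(len(grid))
    if n_realisations > len(grid):
        import warnings

        warnings.warn("scenario D grid exhausted; recycling parameter draws")
    return [grid[order[k % len(grid)]] for k in range(n_realisations)]


def simulate_aux(
    study: SimulatedStudy,
    scenario: SimScenario,
    k: int = 0,
    seed: int | None = None,
) -> np.ndarray:
    """One covariate realisation for the study under the given scenario."""
    m = study.layout.m
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng((seed, k + 1))
    s = scenario.scenario
    if s == "A":
        return rng.uniform(0.0, 1.0, size=m)
    if s == "B":
        # related trait: same causal variants in exactly `shared_blocks`
        # blocks, fresh causal variants (and effects) elsewhere
        shared = rng.choice(study.layout.n_blocks, size=scenario.shared_blocks, replace=False)
        blocks = study.layout.block_of(study.causal_idx)
        keep = np.isin(blocks, shared)
        shared_causal = study.causal_idx[keep]
        sub_layout_blocks = [b for b in range(study.layout.n_blocks) if b not in set(shared.tolist())]
        other = _draw_causals_subset(
            study.layout, scenario.n_causal_choices, rng, sub_layout_blocks,
            avoid=study.causal_idx,
        )
        causal = np.sort(np.concatenate([shared_causal, other]))
        beta = rng.normal(0.0, scenario.effect_sd, size=causal.size)
        gamma = scenario.ncp_scale * beta
        z = _expected_z(study.layout, causal, gamma) + _ar1_noise(study.layout, rng)
        return 2.0 * stats.norm.sf(np.abs(z))
    if s == "C":
        comp = rng.random(m) < 0.5
        return np.where(
            comp, rng.normal(-2.0, 0.5, size=m), rng.normal(3.0, 2.0, size=m)
        )
    functional = np.zeros(m, dtype=bool)
    functional[define_functional_snps(study, scenario.functional_window_bp)] = True
    if s == "D":
        mu1, mu2, w = _d_params_for_study(study, scenario.n_covariate_realisations)[k]
        # functional SNPs put weight w on the low component N(mu2, 0.5^2)
        w_low = np.where(functional, w, 1.0 - w)
        comp_low = rng.random(m) < w_low
        return np.where(
            comp_low,
            rng.normal(mu2, 0.5, size=m),
            rng.normal(mu1, 1.0, size=m),
        )
    # scenario E: fixed distributions across realisations
    return np.where(
        functional,
        rng.normal(-2.0, 0.5, size=m),
        rng.normal(3.0, 2.0, size=m),
    )


def _draw_causals_subset(layout, choices, rng, blocks, avoid):
    avoid = set(int(a) for a in avoid)
    causal = []
    for b in blocks:
        k = int(rng.choice(choices))
        base = b * layout.snps_per_block
        pool = [base + i for i in range(layout.snps_per_block) if base + i not in avoid]
        if k > 0:
            causal.extend(rng.choice(pool, size=k, replace=False))
    return np.asarray(causal, dtype=int)
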