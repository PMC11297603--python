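"""Synthetic multitask chemical-like benchmark generator.

Every other module is testable without any external download because this
generator emulates the structure of a multi-source toxicity compilation:

* **chemical pools** — each pool has a binary prototype bit pattern; a
  chemical is its pool's prototype with per-bit flip noise. ``pool_structure``
  controls which tasks draw from which pools: ``shared`` (all tasks see the
  same chemicals, Tox21-style), ``disjoint`` (task groups with zero chemical
  overlap and separated Tanimoto structure — the distinct-chemical-space
  regime), or ``mixed`` (a tunable overlap fraction with a shared pool).
* **latent label model** — a designated block of signal bits is split into
  ``latent_dim`` groups; the standardized group sums form a latent vector z
  shared by *all* pools. Task t labels chemicals by thresholding
  ``w_t · z + ε`` where ``w_t = ρ·w_shared + (1-ρ)·w_t_private`` (unit
  normalized). ρ = 1 makes all tasks share one labeling rule; ρ = 0 makes
  them independent. Because z is a global function of the bits, cross-task
  signal exists even when pools are disjoint — the phenomenon the cascade
  exploits.
* **imbalance and noise** — the decision threshold τ_t is calibrated by
  quantile so the *realized* positive fraction (after label flips at rate
  ``label_noise``) hits the target; an unreachable target raises.

Determinism: identical configs produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import TaskDataset
from .exceptions import GeneratorError, ValidationError

# mechanism constants (documented in the methods note; not exposed as dials)
PROTOTYPE_DENSITY = 0.1   # P(bit=1) in a pool prototype
BIT_FLIP = 0.15           # per-bit flip probability around the prototype
SIGNAL_BITS_PER_LATENT = 4  # bits per latent dimension (iid Bernoulli(0.5))
MARGIN_NOISE = 0.25       # default sd of the Gaussian ε added to w·z


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic benchmark.

    ``task_relatedness`` is ρ above; ``label_noise`` is the post-threshold
    label flip probability (must be < 0.5); ``positive_fraction`` is the
    target minority/positive rate per task (scalar or one value per task).
    """

    n_tasks: int = 8
    chemicals_per_task: int = 400
    feature_length: int = 1024
    pool_structure: str = "disjoint"  # {shared, disjoint, mixed}
    n_pools: int = 4
    overlap_fraction: float = 0.5  # mixed structure only
    latent_dim: int = 16
    task_relatedness: float = 0.9
    label_noise: float = 0.1
    margin_noise: float = MARGIN_NOISE
    positive_fraction: float | tuple = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        if self.pool_structure not in ("shared", "disjoint", "mixed"):
            raise ValidationError(f"unknown pool_structure {self.pool_structure!r}")
        if not 0 <= self.task_relatedness <= 1:
            raise ValidationError("task_relatedness must be in [0, 1]")
        if not 0 <= self.label_noise < 0.5:
            raise ValidationError("label_noise must be in [0, 0.5)")
        if self.margin_noise < 0:
            raise ValidationError("margin_noise must be >= 0")
        need = self.latent_dim * SIGNAL_BITS_PER_LATENT
        if need > self.feature_length:
            raise ValidationError(
                f"feature_length {self.feature_length} too small for "
                f"latent_dim {self.latent_dim} ({need} signal bits needed)"
            )

    def positive_fractions(self) -> np.ndarray:
        p = self.positive_fraction
        arr = np.full(self.n_tasks, p, float) if np.isscalar(p) else np.asarray(p, float)
        if arr.shape != (self.n_tasks,):
            raise ValidationError("positive_fraction must be scalar or one per task")
        if not ((arr > 0) & (arr < 1)).all():
            raise ValidationError("positive fractions must lie in (0, 1)")
        return arr


@dataclass
class GroundTruth:
    """Everything the generator decided, for oracle-style assertions."""

    config: GeneratorConfig
    pool_of_task: list[int]
    prototypes: np.ndarray          # (n_pools_total, m)
    signal_groups: list[np.ndarray]  # latent_dim index arrays
    w_shared: np.ndarray
    w_task: np.ndarray              # (n_tasks, latent_dim)
    tau: np.ndarray                 # (n_tasks,)
    flip_masks: list[np.ndarray]    # per task, bool
    latent: dict[str, np.ndarray] = field(default_factory=dict)  # chem_id -> z


def _pool_assignment(config: GeneratorConfig) -> tuple[int, list[list[int]]]:
    """Number of pools and, per task, which pools it draws from (with counts
    resolved later). Returns (n_pools_total, pools_per_task)."""
    if config.pool_structure == "shared":
        return 1, [[0] for _ in range(config.n_tasks)]
    if config.pool_structure == "disjoint":
        return config.n_pools, [[t % config.n_pools] for t in range(config.n_tasks)]
    # mixed: pool 0 shared, pool 1+t private per task
    return 1 + config.n_tasks, [[0, 1 + t] for t in range(config.n_tasks)]


def generate(config: GeneratorConfig) -> tuple[list[TaskDataset], GroundTruth]:
    """Generate one multitask benchmark (unsplit tasks) plus its ground truth.

    Tasks assigned to the same pool use the same chemicals (identical ids
    and fingerprints); tasks in different pools share none. In ``mixed``
    structure each task takes ``overlap_fraction`` of its chemicals from the
    shared pool and the rest from a private pool.
    """
    rng = np.random.default_rng(config.seed)
    m = config.feature_length
    gsize = SIGNAL_BITS_PER_LATENT
    perm = rng.permutation(m)
    groups = [perm[j * gsize:(j + 1) * gsize] for j in range(config.latent_dim)]
    signal_bits = np.concatenate(groups)

    n_pools, pools_per_task = _pool_assignment(config)
    prototypes = (rng.random((n_pools, m)) < PROTOTYPE_DENSITY).astype(np.uint8)

    # pool population sizes
    n = config.chemicals_per_task
    pool_size = np.zeros(n_pools, dtype=int)
    if config.pool_structure == "mixed":
        k_shared = int(round(config.overlap_fraction * n))
        pool_size[0] = k_shared
        pool_size[1:] = n - k_shared
    else:
        pool_size[:] = n

    pool_X: list[np.ndarray] = []
    pool_Z: list[np.ndarray] = []
    pool_ids: list[np.ndarray] = []
    for p in range(n_pools):
        sz = int(pool_size[p])
        flips = rng.random((sz, m)) < BIT_FLIP
        X = np.where(flips, 1 - prototypes[p], prototypes[p]).astype(np.uint8)
        # signal bits are iid fair coins for every chemical in every pool,
        # so the latent coordinates are comparable across pools
        X[:, signal_bits] = (rng.random((sz, signal_bits.size)) < 0.5).astype(np.uint8)
        Z = np.stack([X[:, g].sum(1) for g in groups], axis=1).astype(float)
        Z = (Z - gsize / 2) / np.sqrt(gsize / 4)
        pool_X.append(X)
        pool_Z.append(Z)
        pool_ids.append(np.array([f"P{p}_{i:05d}" for i in range(sz)], dtype=object))

    w_shared = rng.normal(size=config.latent_dim)
    w_shared /= np.linalg.norm(w_shared)
    rho = config.task_relatedness
    pos_frac = config.positive_fractions()
    nu = config.label_noise

    tasks: list[TaskDataset] = []
    w_task = np.zeros((config.n_tasks, config.latent_dim))
    tau = np.zeros(config.n_tasks)
    flip_masks: list[np.ndarray] = []
    pool_of_task: list[int] = []
    for t in range(config.n_tasks):
        pools = pools_per_task[t]
        pool_of_task.append(pools[-1])
        X = np.vstack([pool_X[p] for p in pools])
        Z = np.vstack([pool_Z[p] for p in pools])
        ids = np.concatenate([pool_ids[p] for p in pools])
        wp = rng.normal(size=config.latent_dim)
        wp /= np.linalg.norm(wp)
        w = rho * w_shared + (1 - rho) * wp
        w /= np.linalg.norm(w)
        w_task[t] = w
        margin = Z @ w + config.margin_noise * rng.normal(size=len(Z))
        # calibrate the threshold so the post-flip positive fraction hits target
        q = (pos_frac[t] - nu) / (1 - 2 * nu)
        if not 0 < q < 1:
            raise GeneratorError(
                f"task {t}: positive fraction {pos_frac[t]} unreachable under "
                f"label noise {nu}"
            )
        tau[t] = float(np.quantile(margin, 1 - q))
        y = (margin > tau[t]).astype(np.int8)
        flip = rng.random(len(y)) < nu
        y = np.where(flip, 1 - y, y).astype(np.int8)
        flip_masks.append(flip)
        tasks.append(TaskDataset(f"task_{t:02d}", ids, X, y))

    latent = {}
    for p in range(n_pools):
        for cid, z in zip(pool_ids[p], pool_Z[p]):
            latent[cid] = z
    truth = GroundTruth(
        config=config,
        pool_of_task=pool_of_task,
        prototypes=prototypes,
        signal_groups=groups,
        w_shared=w_shared,
        w_task=w_task,
        tau=tau,
        flip_masks=flip_masks,
        latent=latent,
    )
    return tasks, truth


def sample_chemicals(
    truth: GroundTruth,
    n_per_pool: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw fresh chemicals from an existing benchmark's generative process.

    Uses the stored pool prototypes and signal-bit scheme with a new seed,
    so the returned chemicals follow the same distribution as the original
    benchmark but were never seen by any model trained on it. Returns
    (chem_ids, X, Z) stacked over all pools.
    """
    rng = np.random.default_rng(seed)
    m = truth.config.feature_length
    gsize = SIGNAL_BITS_PER_LATENT
    groups = truth.signal_groups
    signal_bits = np.concatenate(groups)
    ids, Xs, Zs = [], [], []
    for p in range(truth.prototypes.shape[0]):
        flips = rng.random((n_per_pool, m)) < BIT_FLIP
        X = np.where(flips, 1 - truth.prototypes[p], truth.prototypes[p]).astype(np.uint8)
        X[:, signal_bits] = (rng.random((n_per_pool, signal_bits.size)) < 0.5).astype(np.uint8)
        Z = np.stack([X[:, g].sum(1) for g in groups], axis=1).astype(float)
        Z = (Z - gsize / 2) / np.sqrt(gsize / 4)
        ids.append(np.array([f"N{p}_{i:05d}" for i in range(n_per_pool)], dtype=object))
        Xs.append(X)
        Zs.append(Z)
    return np.concatenate(ids), np.vstack(Xs), np.vstack(Zs)


def transfer_benchmark_config(seed: int = 7, rho: float = 0.9) -> GeneratorConfig:
    """The standard transfer benchmark: 8 tasks of 400 chemicals over 4
    disjoint pools, 16 latent dimensions, 10% label noise.

    The fingerprint length is 256 bits — at the log2 max-features rule this
    keeps the per-split probability of seeing signal bits high enough for
    forests to learn at desk scale, and keeps the 10-replicate benchmark
    fast on one CPU.
    """
    return GeneratorConfig(
        n_tasks=8,
        chemicals_per_task=400,
        feature_length=256,
        pool_structure="disjoint",
        n_pools=4,
        latent_dim=16,
        task_relatedness=rho,
        label_noise=0.1,
        positive_fraction=0.3,
        seed=seed,
    )


def with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Same configuration, different replicate seed."""
    return replace(config, seed=seed)


#: Fixed roster of valid drug-like SMILES for I/O round-trip fixtures.
#: These are real structures of common drugs/agrochemicals; the *binary
#: fingerprints produced by generate() are synthetic and are NOT claimed to
#: correspond to these molecules*.
DRUGLIKE_SMILES: list[str] = [
    "CC(=O)Oc1ccccc1C(=O)O",                      # aspirin
    "CC(=O)Nc1ccc(O)cc1",                         # paracetamol
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",                 # ibuprofen
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",               # caffeine
    "Clc1ccccc1-c1nc2ccccc2[nH]1",                # benzimidazole deriv.
    "CCO",                                        # ethanol
    "c1ccccc1",                                   # benzene
    "OC(=O)c1ccccc1O",                            # salicylic acid
    "Nc1ccc(cc1)S(N)(=O)=O",                      # sulfanilamide
    "CN(C)CCOC(c1ccccc1)c1ccccc1",                # diphenhydramine
    "CC(N)Cc1ccccc1",                             # amphetamine
    "OCC(O)CO",                                   # glycerol
    "CC(=O)OCC[N+](C)(C)C",                       # acetylcholine
    "NCCc1ccc(O)c(O)c1",                          # dopamine
    "OC(=O)CCc1ccccc1",                           # hydrocinnamic acid
    "Clc1ccc(cc1)C(c1ccc(Cl)cc1)C(Cl)(Cl)Cl",     # DDT
    "CO",                                         # methanol
    "CCN(CC)CC",                                  # triethylamine
    "Oc1ccc(Cl)cc1",                              # 4-chlorophenol
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",             # atenolol
    "CN1CCC[C@H]1c1cccnc1",                       # nicotine
    "OC(=O)c1cc(O)c(O)c(O)c1",                    # gallic acid
    "CCOC(=O)c1ccccc1",                           # ethyl benzoate
    "Nc1ncnc2[nH]cnc12",                          # adenine
    "Cn1cnc2c1c(=O)[nH]c(=O)n2C",                 # theobromine
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",             # estradiol
    "OCC1OC(O)C(O)C(O)C1O",                       # glucose
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",              # salbutamol
    "O=C(O)c1ccccc1Nc1cccc(C(F)(F)F)c1",          # flufenamic acid
    "COc1cc2c(cc1OC)CCN(C)CC2",                   # tetrahydroisoquinoline
    "CC(C)C1CCC(C)CC1O",                          # menthol
    "O=Cc1ccc(O)c(OC)c1",                         # vanillin
    "CSCCC(N)C(=O)O",                             # methionine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",                # tryptophan
    "OC(=O)C=Cc1ccccc1",                          # cinnamic acid
    "ClCCN(CCCl)N=O",                             # nitrosamine mustard
    "Oc1ccccc1O",                                 # catechol
    "NC(=O)c1ccc[nH+]c1",                         # nicotinamide cation
    "CCCCCCCCCCCCCCCC(=O)O",                      # palmitic acid
    "Nc1ccccc1",                                  # aniline
    "O=[N+]([O-])c1ccccc1",                       # nitrobenzene
    "CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C",   # progesterone
    "OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc23)CC1",   # perphenazine-like
    "CC1=CC(=O)CC(C)(C)C1",                       # isophorone
    "COC(=O)c1ccccc1O",                           # methyl salicylate
    "NCCCC[C@H](N)C(=O)O",                        # lysine
    "CC(C)=CCCC(C)=CCO",                          # geraniol
    "c1ccc2c(c1)ccc1ccccc21",                     # phenanthrene
    "Oc1cccc2ccccc12",                            # 1-naphthol
    "CN(C)C(=N)NC(=N)N",                          # metformin
]


def example_chemical_records(n: int = 5):
    """ChemicalRecords over the fixed SMILES roster, with toy endpoint values
    (deterministic), for I/O round-trip tests."""
    from .io_featurize import ChemicalRecord

    if not 1 <= n <= len(DRUGLIKE_SMILES):
        raise ValidationError(f"n must be in [1, {len(DRUGLIKE_SMILES)}]")
    records = []
    for i, smi in enumerate(DRUGLIKE_SMILES[:n]):
        records.append(
            ChemicalRecord(
                chem_id=f"FIX{i:03d}",
                smiles=smi,
                endpoint_values={"BMD10": round(0.1 + 0.35 * i, 3), "LEL": float(10 * (i + 1))},
            )
        )
    return records
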