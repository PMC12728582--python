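"""Synthetic rhizosphere dataset generator.

Emulates the statistical structure the downstream analysis assumes: a
factorial design of treatments x replicates, two kingdoms of ASVs whose
log-abundances co-fluctuate within guild "blocks" with a treatment-dependent
latent correlation (higher correlation => denser detectable co-occurrence
structure), and a panel of soil-function measurements driven linearly by the
sample's latent connectivity.

Generative model, fully seeded:

1. baseline log-abundance per ASV: ``a_i ~ N(0, base_log_sd^2)`` (log-normal
   mean abundances);
2. per-sample deviations from a block-structured latent factor model:
   ``z_is = dev_sd * (sqrt(rho_t) * f_{b(i),s} + sqrt(1 - rho_t) * e_is)``
   with ``f, e ~ N(0,1)`` iid, so within-block correlation is exactly
   ``rho_t``, the treatment's block correlation, and zero across blocks;
   blocks are assigned round-robin over both kingdoms jointly so the combined
   network has cross-kingdom structure;
3. counts per kingdom drawn ``Multinomial(library_size, softmax(a + z))``
   (an overdispersion option interposes Dirichlet noise);
4. latent sample connectivity ``c_s = rho_t + N(0, jitter)``, jitter 0.02 so
   connectivity varies within treatment and sample-level regressions are
   possible;
5. function values ``f_sj = mu_j + beta_c * c_s * sigma_j + N(0, noise_sd *
   sigma_j)`` where ``mu_j, sigma_j`` are per-function location/scale chosen
   so outputs are unit-plausible for black-soil topsoil (e.g. SOC ~ 19.2
   g/kg); the scales are cosmetic, not fitted.

The returned ground truth records ``c_s``, block memberships and ``beta_c``
so recovery of the treatment -> connectivity -> multifunctionality chain can
be tested end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AsvTable, CANONICAL_FUNCTIONS, FunctionMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "SyntheticDataset", "generate_dataset", "generate_tree"]

# location/scale per canonical function (measurement units; see module docstring)
FUNCTION_SCALES: dict[str, tuple[float, float]] = {
    "ALP": (25.0, 5.0),   # alkaline phosphatase, umol/d/g
    "AP": (7.9, 1.5),     # available P, mg/kg
    "TP": (1.04, 0.15),   # total P, g/kg
    "MBP": (15.0, 3.0),   # microbial biomass P, mg/kg
    "AN": (12.0, 2.5),    # ammonium N, mg/kg
    "NN": (18.0, 4.0),    # nitrate N, mg/kg
    "MBN": (45.0, 8.0),   # microbial biomass N, mg/kg
    "TN": (1.4, 0.2),     # total N, g/kg
    "Ure": (30.0, 6.0),   # urease, ug/d/g
    "MBC": (320.0, 50.0), # microbial biomass C, mg/kg
    "SOC": (19.2, 2.5),   # soil organic C, g/kg
    "SSC": (40.0, 8.0),   # sucrase, mg/d/g
}

DEFAULT_TREATMENTS = ("CK", "SBSH", "SBSF")


@dataclass
class SynthConfig:
    """Configuration of the generative model; defaults mirror the field design
    of three straw-returning treatments x three replicates."""

    n_treatments: int = 3
    n_replicates: int = 3
    n_bacteria_asvs: int = 150
    n_fungi_asvs: int = 60
    library_size_bacteria: int = 20_000
    library_size_fungi: int = 8_000
    n_blocks: int = 5
    block_rho_by_treatment: tuple[float, ...] = (0.2, 0.5, 0.8)
    complexity_effect: float = 2.0  # beta_c
    noise_sd: float = 0.2
    base_log_sd: float = 1.0
    dev_sd: float = 2.0
    connectivity_jitter: float = 0.02
    overdispersion: float | None = None  # Dirichlet precision; None = plain multinomial
    treatments: tuple[str, ...] = field(default=())
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_treatments < 2 or self.n_replicates < 1:
            raise ValueError("need >=2 treatments and >=1 replicate")
        if self.n_treatments * self.n_replicates < 2:
            raise ValueError("degenerate design: fewer than 2 samples")
        if len(self.block_rho_by_treatment) != self.n_treatments:
            raise ValueError("block_rho_by_treatment must have one value per treatment")
        if not all(0 <= r < 1 for r in self.block_rho_by_treatment):
            raise ValueError("block correlations must lie in [0, 1)")
        for size, n, king in (
            (self.library_size_bacteria, self.n_bacteria_asvs, "bacteria"),
            (self.library_size_fungi, self.n_fungi_asvs, "fungi"),
        ):
            if n < 1 or size < 1:
                raise ValueError("ASV and library counts must be positive")
            if size < 10 * n:
                logger.warning(
                    "%s library size %d is < 10x the %d ASVs; counts will be sparse",
                    king, size, n,
                )
        if not self.treatments:
            if self.n_treatments == len(DEFAULT_TREATMENTS):
                self.treatments = DEFAULT_TREATMENTS
            else:
                self.treatments = tuple(f"T{i + 1}" for i in range(self.n_treatments))
        if len(self.treatments) != self.n_treatments:
            raise ValueError("treatment label count mismatch")


@dataclass
class SyntheticDataset:
    bacteria: AsvTable
    fungi: AsvTable
    functions: FunctionMatrix
    metadata: SampleMetadata
    ground_truth: pd.DataFrame      # per sample: treatment, block_rho, connectivity
    block_membership: dict[str, int]
    beta_c: float


def _taxonomy(asv_ids: list[str], kingdom: str, blocks: dict[str, int]) -> dict[str, list[str]]:
    """Toy lineages: phylum follows the guild block, genus groups ~4 ASVs."""
    domain = "Bacteria" if kingdom == "bacteria" else "Fungi"
    tax = {}
    for i, asv in enumerate(asv_ids):
        b = blocks[asv]
        tax[asv] = [
            f"d__{domain}",
            f"p__Phylum{b}",
            f"c__Class{b}",
            f"o__Order{b}",
            f"f__Family{i // 8}",
            f"g__Genus_{kingdom[0]}{i // 4}",
        ]
    return tax


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Draw one dataset from the generative model (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n_b, n_f = config.n_bacteria_asvs, config.n_fungi_asvs
    n_asvs = n_b + n_f
    asv_ids = [f"B{i:04d}" for i in range(n_b)] + [f"F{i:04d}" for i in range(n_f)]
    kingdoms = np.array(["bacteria"] * n_b + ["fungi"] * n_f)

    sample_ids, treat_of_sample = [], []
    for t in config.treatments:
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"{t}.{r}")
            treat_of_sample.append(t)
    n_samples = len(sample_ids)
    rho_of_treatment = dict(zip(config.treatments, config.block_rho_by_treatment))

    block = np.arange(n_asvs) % config.n_blocks  # round-robin across both kingdoms
    base = rng.normal(0.0, config.base_log_sd, size=n_asvs)

    counts = np.zeros((n_asvs, n_samples), dtype=np.int64)
    connectivity = np.empty(n_samples)
    for s, (sid, t) in enumerate(zip(sample_ids, treat_of_sample)):
        rho = rho_of_treatment[t]
        factors = rng.normal(size=config.n_blocks)
        noise = rng.normal(size=n_asvs)
        z = config.dev_sd * (np.sqrt(rho) * factors[block] + np.sqrt(1.0 - rho) * noise)
        logits = base + z
        for king, lib in (("bacteria", config.library_size_bacteria),
                          ("fungi", config.library_size_fungi)):
            mask = kingdoms == king
            p = np.exp(logits[mask] - logits[mask].max())
            p /= p.sum()
            if config.overdispersion is not None:
                p = rng.dirichlet(p * config.overdispersion)
            counts[mask, s] = rng.multinomial(lib, p)
        connectivity[s] = rho + rng.normal(0.0, config.connectivity_jitter)

    block_membership = dict(zip(asv_ids, (int(b) for b in block)))
    counts_df = pd.DataFrame(counts, index=asv_ids, columns=sample_ids)
    tables = {}
    for king in ("bacteria", "fungi"):
        mask = kingdoms == king
        ids = [a for a, m in zip(asv_ids, mask) if m]
        tables[king] = AsvTable(
            counts=counts_df.loc[ids],
            kingdom=king,
            taxonomy=_taxonomy(ids, king, block_membership),
        )

    fn_names = list(CANONICAL_FUNCTIONS)
    mu = np.array([FUNCTION_SCALES[f][0] for f in fn_names])
    sigma = np.array([FUNCTION_SCALES[f][1] for f in fn_names])
    eps = rng.normal(0.0, 1.0, size=(n_samples, len(fn_names)))
    values = (
        mu[None, :]
        + config.complexity_effect * connectivity[:, None] * sigma[None, :]
        + config.noise_sd * sigma[None, :] * eps
    )
    functions = FunctionMatrix(values=pd.DataFrame(values, index=sample_ids, columns=fn_names))

    metadata = SampleMetadata(table=pd.DataFrame(
        {
            "treatment": treat_of_sample,
            "replicate": [int(s.rsplit(".", 1)[1]) for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    ground_truth = pd.DataFrame(
        {
            "treatment": treat_of_sample,
            "block_rho": [rho_of_treatment[t] for t in treat_of_sample],
            "connectivity": connectivity,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticDataset(
        bacteria=tables["bacteria"],
        fungi=tables["fungi"],
        functions=functions,
        metadata=metadata,
        ground_truth=ground_truth,
        block_membership=block_membership,
        beta_c=config.complexity_effect,
    )


def generate_tree(asv_ids, seed: int | None = None) -> str:
    """Random coalescent-style bifurcating tree over the given tips, returned
    as a Newick string with strictly positive branch lengths."""
    tips = list(asv_ids)
    if len(tips) < 2:
        raise ValueError("need at least 2 tips")
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip ids")
    rng = np.random.default_rng(seed)
    # successive pairwise coalescence with exponential waiting times
    nodes = [(tip, 0.0) for tip in tips]
    k = len(nodes)
    height = 0.0
    while len(nodes) > 1:
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(len(nodes), size=2, replace=False)
        (ni, hi), (nj, hj) = nodes[i], nodes[j]
        merged = f"({ni}:{height - hi:.10g},{nj}:{height - hj:.10g})"
        nodes = [nodes[m] for m in range(len(nodes)) if m not in (i, j)]
        nodes.append((merged, height))
        k -= 1
    return nodes[0][0] + ";"
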