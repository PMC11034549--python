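"""End-to-end synthesis: long table in, synthetic long table + report out.

Stages (each optional piece gated by the config):

1. tensorize the long records; determine per-patient visit counts when
   irregular-visit handling is on;
2. standardize each variable over observed entries;
3. fit the generalized CP model to the value tensor (rank R, chosen loss);
4. if any cell is unobserved, fit a second Gaussian-loss CP model of rank
   R' to the binary mask tensor;
5. assemble the augmented latent table: GCP patient factors + mask-tensor
   patient factors + visit-count column, jointly sampled so that
   cross-dependence between values, missingness and visit counts survives;
6. sample n_out synthetic patients with the configured sampler (copula,
   sequential trees, or HMC);
7. reconstruct the synthetic value tensor from the sampled patient factors
   and the *fitted* variable/visit factors; reconstruct the synthetic mask
   the same way and binarize at the configured threshold;
8. destandardize, apply the synthetic mask, truncate each synthetic patient
   to its (rounded, clipped) synthetic visit count, round-and-clip
   categorical variables, and emit fresh `synth-NNNNNN` patient ids.

The paired utility report compares the input and output tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .copula import CopulaSpec, copula_sample
from .errors import GcpsynthError
from .fit import FitOptions, fit_gcp, select_rank
from .hmc import HmcSpec, hmc_fit, hmc_sample
from .latent import AugmentedLatent, LatentTable, augment_latent
from .longio import LongTable, long_to_tensor, tensor_to_long
from .losses import LossSpec
from .metrics import UtilityReport, evaluate_utility
from .seqtrees import TreeOptions, seqtree_fit, seqtree_sample
from .tensor import KruskalModel, Tensor3, destandardize, reconstruct, standardize

__all__ = [
    "SynthesisConfig",
    "build_mask",
    "regularize_visits",
    "postprocess_categorical",
    "synthesize",
]

log = logging.getLogger(__name__)

SAMPLERS = ("copula", "seqtrees", "hmc")


@dataclass
class SynthesisConfig:
    """All knobs of the end-to-end pipeline (mirrors the CLI config file)."""

    loss: LossSpec = field(default_factory=LossSpec)
    rank: int | list[int] = 8
    mask_rank: int = 4
    sampler: str = "seqtrees"
    n_out: int | None = None  # default: same patient count as the input
    standardize: bool = True
    model_missingness: bool = True
    irregular_visits: bool = False
    categorical_levels: dict[str, list[int]] = field(default_factory=dict)
    clamp_to_observed: bool = False
    mask_threshold: float = 0.5
    plateau: float = 0.01
    seed: int = 0
    fit_options: FitOptions | None = None
    copula: CopulaSpec | None = None
    trees: TreeOptions | None = None
    hmc: HmcSpec | None = None
    hmc_allow_non_gaussian: bool = False
    corr_method: str = "pearson"

    def __post_init__(self) -> None:
        if self.sampler not in SAMPLERS:
            raise ValueError(f"sampler must be one of {SAMPLERS}")
        if isinstance(self.rank, int) and self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.mask_rank < 1:
            raise ValueError("mask rank must be >= 1")
        if self.n_out is not None and self.n_out < 1:
            raise ValueError("n_out must be >= 1")


def build_mask(table: LongTable) -> Tensor3:
    """Tensorize the long records (mask 1 iff a non-empty value exists)."""
    return long_to_tensor(table)


def regularize_visits(table: LongTable) -> tuple[Tensor3, np.ndarray]:
    """Tensorize an irregular table; return per-patient observed visit counts.

    A patient's visit count v_i is the largest visit index at which any
    variable was observed; cells beyond v_i stay masked.  K is max_i v_i.
    """
    t = long_to_tensor(table)
    any_obs = t.observed.any(axis=1)  # patients x visits
    if not any_obs.any(axis=1).all():
        bad = [t.patient_ids[i] for i in np.where(~any_obs.any(axis=1))[0][:5]]
        raise GcpsynthError(f"patients with no observed visits: {bad}")
    counts = np.array([int(np.max(np.where(row)[0])) + 1 for row in any_obs])
    return t, counts


def postprocess_categorical(
    values: np.ndarray, levels: list[int], poisson_log: bool = False
) -> np.ndarray:
    """Round to the nearest admissible integer code and clip into range.

    Poisson-log-link reconstructions are exponentiated first (the model
    value is the log-rate).
    """
    if len(levels) == 0:
        raise ValueError("empty category level set")
    v = np.asarray(values, dtype=float)
    if poisson_log:
        v = np.exp(v)
    lo, hi = min(levels), max(levels)
    return np.clip(np.rint(v), lo, hi)


def _sample_latent(
    aug: AugmentedLatent, n_out: int, config: SynthesisConfig
) -> tuple[AugmentedLatent, dict]:
    table = aug.table
    meta: dict = {"sampler": config.sampler}
    if config.sampler == "copula":
        spec = config.copula or CopulaSpec(random_seed=config.seed)
        res = copula_sample(table, n_out, spec)
        meta.update(
            {
                "copula_accepted": res.accepted,
                "copula_tries": res.tries,
                "copula_frobenius": res.frobenius_distance,
            }
        )
        out = res.table
    elif config.sampler == "seqtrees":
        opts = config.trees or TreeOptions(random_seed=config.seed)
        model = seqtree_fit(table, opts)
        out = seqtree_sample(model, n_out, seed=config.seed)
    else:
        spec = config.hmc or HmcSpec(random_seed=config.seed)
        posterior = hmc_fit(table, spec, allow_non_gaussian=config.hmc_allow_non_gaussian)
        meta.update(
            {
                "hmc_max_rhat": float(np.max(posterior.rhat)),
                "hmc_min_ess": float(np.min(posterior.ess)),
                "hmc_warnings": posterior.warnings,
            }
        )
        out = hmc_sample(posterior, n_out, seed=config.seed)
    return aug.with_table(out), meta


def synthesize(
    table: LongTable, config: SynthesisConfig | None = None
) -> tuple[LongTable, UtilityReport]:
    """Run the full pipeline and return (synthetic table, utility report)."""
    config = config or SynthesisConfig()
    stages: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(name: str) -> None:
        """Record the just-completed stage's wall time."""
        nonlocal t0
        now = time.perf_counter()
        stages[name] = now - t0
        log.info("stage %-22s %.2fs", name, stages[name])
        t0 = now

    sequence = [
        "tensorize",
        "standardize",
        "fit_gcp",
        "fit_mask",
        "sample",
        "reconstruct",
        "postprocess",
        "evaluate",
    ]
    try:
        return _synthesize_impl(table, config, tick, stages)
    except GcpsynthError:
        raise
    except Exception as exc:
        in_progress = sequence[min(len(stages), len(sequence) - 1)]
        raise GcpsynthError(f"stage {in_progress!r} failed: {exc}") from exc


def _synthesize_impl(table, config, tick, stages):

    # -- tensorize ---------------------------------------------------------
    visit_counts: np.ndarray | None = None
    if config.irregular_visits:
        x, visit_counts = regularize_visits(table)
    else:
        x = build_mask(table)
    I, J, K = x.shape
    n_out = config.n_out or I
    tick("tensorize")

    # -- standardize -------------------------------------------------------
    transform = None
    if config.standardize:
        x_fit, transform = standardize(x)
    else:
        x_fit = x
    tick("standardize")

    # -- fit the value tensor ---------------------------------------------
    fit_opts = config.fit_options or FitOptions(random_seed=config.seed)
    if isinstance(config.rank, list):
        rank, _ = select_rank(x_fit, config.rank, config.loss, fit_opts, config.plateau)
    else:
        rank = config.rank
    model = fit_gcp(x_fit, rank, config.loss, fit_opts).with_absorbed_weights()
    a, b, c = model.factors
    gcp_latent = LatentTable(
        pd.DataFrame(a, columns=[f"a{r + 1}" for r in range(rank)]),
        provenance_loss=config.loss.name,
    )
    tick("fit_gcp")

    # -- fit the mask tensor ----------------------------------------------
    mask_model: KruskalModel | None = None
    mask_latent: LatentTable | None = None
    has_missing = bool((x.mask == 0).any())
    if has_missing and config.model_missingness:
        w = Tensor3(
            x.mask.copy(),
            np.ones_like(x.mask),
            list(x.patient_ids),
            list(x.variable_names),
            list(x.visit_indices),
        )
        mask_model = fit_gcp(
            w, config.mask_rank, LossSpec("gaussian"), fit_opts
        ).with_absorbed_weights()
        aw = mask_model.factors[0]
        mask_latent = LatentTable(
            pd.DataFrame(aw, columns=[f"w{r + 1}" for r in range(config.mask_rank)]),
            provenance_loss="gaussian",
        )
    tick("fit_mask")

    # -- augment + sample --------------------------------------------------
    aug = augment_latent(gcp_latent, mask_latent, visit_counts)
    sampled, sampler_meta = _sample_latent(aug, n_out, config)
    parts = sampled.split()
    tick("sample")

    # -- reconstruct -------------------------------------------------------
    a_syn = parts["gcp_factors"].values()
    syn_values = np.einsum("ir,jr,kr->ijk", a_syn, b, c)
    syn_mask = np.ones((n_out, J, K))
    if mask_model is not None:
        bw, cw = mask_model.factors[1], mask_model.factors[2]
        aw_syn = parts["mask_factors"].values()
        syn_mask = (
            np.einsum("ir,jr,kr->ijk", aw_syn, bw, cw) >= config.mask_threshold
        ).astype(float)

    syn = Tensor3(
        np.where(syn_mask > 0.5, syn_values, np.nan),
        syn_mask,
        [f"synth-{i + 1:06d}" for i in range(n_out)],
        list(x.variable_names),
        list(x.visit_indices),
    )
    if transform is not None:
        syn = destandardize(syn, transform)
    tick("reconstruct")

    # -- postprocess -------------------------------------------------------
    if "visit_count" in parts:
        v_syn = np.clip(np.floor(parts["visit_count"].values().ravel() + 0.5), 1, K)
        for i in range(n_out):
            syn.mask[i, :, int(v_syn[i]) :] = 0.0
        syn.values[~syn.observed] = np.nan
    for var, levels in config.categorical_levels.items():
        if var in syn.variable_names:
            j = syn.variable_names.index(var)
            syn.values[:, j, :] = postprocess_categorical(
                syn.values[:, j, :], levels, poisson_log=config.loss.name == "poisson_log"
            )
    if config.clamp_to_observed:
        for j in range(J):
            obs = x.values[:, j, :][x.observed[:, j, :]]
            syn.values[:, j, :] = np.clip(syn.values[:, j, :], obs.min(), obs.max())
    syn.values[~syn.observed] = np.nan
    out_table = tensor_to_long(syn, include_missing=has_missing)
    tick("postprocess")

    # -- evaluate ----------------------------------------------------------
    report = evaluate_utility(
        table,
        out_table,
        corr_method=config.corr_method,
        categorical_variables=set(config.categorical_levels),
        metadata={
            "seed": config.seed,
            "rank": rank,
            "mask_rank": config.mask_rank if mask_model is not None else None,
            "loss": config.loss.name,
            "n_out": n_out,
            "stage_seconds": stages,
            **sampler_meta,
        },
    )
    tick("evaluate")
    return out_table, report
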