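"""Synthetic two-class paired expression data.

The generator emulates the study substrate: an RPKM-like positive expression
matrix for two perfectly balanced classes in a paired case/control design,
with a controllable number of informative features, controllable class
separability and block-correlation structure.

Model (log2 scale), for sample i and feature f::

    log2 x[i, f] = baseline[f] + a[pair(i)] + delta[i, f] + noise_sd * z[i, f]

* ``baseline[f]`` ~ Uniform(3, 8): per-feature mean log2 abundance.
* ``a[p]`` ~ Normal(0, pair_sd): shared per-pair intercept — the mechanism
  that makes the two members of a pair resemble each other. Defaults to 0 so
  that feature–feature correlation is governed by the block structure alone.
* ``delta[i, f] = effect_size * noise_sd`` for cases on the first
  ``n_informative`` features, else 0: the class separation, expressed in
  units of the noise standard deviation.
* ``z[i, f]`` standard normal with block-diagonal correlation: consecutive
  blocks of ``block_size`` features share a factor so that any two features
  in a block correlate at ``within_block_corr``.

Values are exponentiated (base 2), so the output is strictly positive and
right-skewed like RPKM data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionDataset
from .errors import ParameterError

CASE_LABEL = "tumor"
CONTROL_LABEL = "healthy"


def generate(
    n_pairs: int,
    n_features: int,
    n_informative: int,
    effect_size: float = 1.0,
    block_size: int = 1,
    within_block_corr: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    pair_sd: float = 0.0,
) -> ExpressionDataset:
    """Generate a balanced paired two-class RPKM-like dataset.

    Returns ``2 * n_pairs`` samples (one case + one control per pair id);
    deterministic under ``seed``. The declared positive class is the case
    (tumour) label.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    if not 0 <= n_informative <= n_features:
        raise ParameterError("need 0 <= n_informative <= n_features")
    if not 0.0 <= within_block_corr < 1.0:
        raise ParameterError("within_block_corr must lie in [0, 1)")
    if effect_size < 0:
        raise ParameterError("effect_size must be >= 0")
    if block_size < 1:
        raise ParameterError("block_size must be >= 1")
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be > 0")

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_pairs

    baseline = rng.uniform(3.0, 8.0, size=n_features)

    # Block-correlated standard-normal noise: z = sqrt(rho)*g_block + sqrt(1-rho)*e
    block_of = np.arange(n_features) // block_size
    n_blocks = int(block_of.max()) + 1
    g = rng.standard_normal((n_samples, n_blocks))
    e = rng.standard_normal((n_samples, n_features))
    rho = within_block_corr
    z = np.sqrt(rho) * g[:, block_of] + np.sqrt(1.0 - rho) * e

    pair_intercept = rng.normal(0.0, pair_sd, size=n_pairs) if pair_sd > 0 else np.zeros(n_pairs)

    # Sample layout: pair p contributes rows 2p (case) and 2p+1 (control).
    labels = np.empty(n_samples, dtype=object)
    labels[0::2] = CASE_LABEL
    labels[1::2] = CONTROL_LABEL
    pair_ids = [f"P{p:04d}" for p in range(n_pairs) for _ in range(2)]
    sample_ids = [
        f"P{p:04d}_{suffix}" for p in range(n_pairs) for suffix in ("tumor", "healthy")
    ]

    shift = np.zeros((n_samples, n_features))
    shift[0::2, :n_informative] = effect_size * noise_sd

    log2x = (
        baseline[None, :]
        + np.repeat(pair_intercept, 2)[:, None]
        + shift
        + noise_sd * z
    )
    return ExpressionDataset(
        values=np.exp2(log2x),
        labels=labels,
        sample_ids=sample_ids,
        feature_ids=[f"g{f:05d}" for f in range(n_features)],
        pair_ids=pair_ids,
        positive_label=CASE_LABEL,
        rpkm_like=True,
    )


@dataclass(frozen=True)
class SyntheticProfile:
    """A named generator preset mirroring one of the study cohort shapes.

    ``n_features`` equals ``n_selected_features``: the preset emulates the
    post-feature-selection matrix, so the signature planner runs directly on
    its feature set.
    """

    name: str
    n_pairs: int
    n_selected_features: int
    effect_size: float
    block_size: int = 3
    within_block_corr: float = 0.4

    @property
    def n_samples(self) -> int:
        return 2 * self.n_pairs

    def generate(self, seed: int = 0) -> ExpressionDataset:
        return generate(
            n_pairs=self.n_pairs,
            n_features=self.n_selected_features,
            n_informative=self.n_selected_features,
            effect_size=self.effect_size,
            block_size=self.block_size,
            within_block_corr=self.within_block_corr,
            noise_sd=1.0,
            seed=seed,
        )


def generate_paper_scale_profiles() -> dict[str, SyntheticProfile]:
    """Presets mirroring the three cohort shapes of the original study.

    brca-like: 182 samples, 28 selected features -> 78 planned signatures;
    lusc-like: 96 samples, 9 -> 21; thca-like: 98 samples, 38 -> 108.
    Effect sizes are set so brca/lusc are cleanly separable while thca-like,
    whose feature count approaches its training-sample count, is noisier.
    """
    profiles = [
        SyntheticProfile("brca_like", n_pairs=91, n_selected_features=28, effect_size=3.0),
        SyntheticProfile("lusc_like", n_pairs=48, n_selected_features=9, effect_size=3.0),
        SyntheticProfile("thca_like", n_pairs=49, n_selected_features=38, effect_size=1.0),
    ]
    return {p.name: p for p in profiles}
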