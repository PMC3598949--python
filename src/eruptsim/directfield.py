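"""Direct per-element field sampling for analysis-stage testing.

Emulates the qualitative structure of a solved follicle field — broadly
compressive hydrostatic stress over the crown and tensile stress beneath
the roots — without running a solve: coronal and apical stresses are drawn
from normal distributions with opposite-signed means, element volumes from
a log-normal, and BRU follows as stress x volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = ["DirectFieldParams", "sample_direct_fields"]


@dataclass
class DirectFieldParams:
    """Sampling distributions for a synthetic cap field.

    Stresses are MPa (negative = compression); volumes mm^3, drawn
    log-normal with the given log-mean and log-sd, hence strictly positive.
    """

    n_coronal: int = 5000
    n_apical: int = 5000
    mu_c: float = -0.02
    mu_a: float = 0.02
    sigma: float = 0.005
    volume_log_mean: float = -3.0
    volume_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coronal < 1 or self.n_apical < 1:
            raise ValueError("element counts must be at least 1")
        if self.sigma < 0:
            raise ValueError("stress spread sigma must be non-negative")
        if self.volume_log_sd < 0:
            raise ValueError("volume_log_sd must be non-negative")


def _sample_one(rng: np.random.Generator, n: int, mu: float, p: DirectFieldParams) -> pd.DataFrame:
    sigma_h = rng.normal(mu, p.sigma, size=n)
    volume = rng.lognormal(p.volume_log_mean, p.volume_log_sd, size=n)
    return pd.DataFrame(
        {
            "element": np.arange(n),
            "region": "follicle_pdl",
            "volume": volume,
            "sigma_h": sigma_h,
            "S_e": np.zeros(n),
            "bru": sigma_h * volume,
        }
    )


def sample_direct_fields(params: DirectFieldParams) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (coronal, apical) element-record tables from the stated
    distributions.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    coronal = _sample_one(rng, params.n_coronal, params.mu_c, params)
    apical = _sample_one(rng, params.n_apical, params.mu_a, params)
    return coronal, apical
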