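"""Deviance information criterion (DIC) for MSV and diagonal-SV fits.

The deviance uses the conditional likelihood P(y | θ, x) with the latent
log-volatility treated as parameters (focus on the latent level):

    D̄        = E_{θ,x|y}[ −2 log P(y | θ, x) ]     (goodness of fit)
    p_D      = D̄ − D(θ̄, x̄)                        (effective #parameters)
    DIC      = D̄ + p_D

Lower DIC is better.  To compare subjects with different amounts of data the
MSV-vs-SV difference is normalized by events × electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import observation_loglik
from .mcmc import PosteriorDraws, posterior_summary
from .preprocessing import EpochedData

__all__ = ["DICResult", "compute_dic", "normalized_dic_difference",
           "dic_probability_ratio"]


@dataclass
class DICResult:
    dbar: float
    d_at_means: float
    p_d: float
    dic: float
    n_events: int
    n_electrodes: int

    def __post_init__(self) -> None:
        assert np.isclose(self.dic, self.dbar + self.p_d)
        assert np.isclose(self.p_d, self.dbar - self.d_at_means)


def compute_dic(draws: PosteriorDraws, data: EpochedData | np.ndarray
                ) -> DICResult:
    """DIC from stored (thinned) latent draws and the posterior-mean latents.

    D̄ averages −2·loglik over the stored draws (the conditional likelihood
    depends on θ only through x, so the stored per-draw log-likelihoods are
    exactly the required deviances); D(θ̄, x̄) evaluates at the posterior
    means.
    """
    y = data.data if isinstance(data, EpochedData) else np.asarray(data)
    if draws.latent_loglik is None or draws.latent_mean is None:
        raise ValueError("DIC needs draws with stored latent paths "
                         "(run_mcmc(..., latent_thin>0))")
    dbar = float(np.mean(-2.0 * draws.latent_loglik))
    _, latents = posterior_summary(draws)
    d_hat = -2.0 * observation_loglik(y, latents.x)
    p_d = dbar - d_hat
    return DICResult(dbar=dbar, d_at_means=d_hat, p_d=p_d, dic=dbar + p_d,
                     n_events=y.shape[0], n_electrodes=y.shape[1])


def normalized_dic_difference(dic_msv: float, dic_sv: float,
                              n_events: int, n_electrodes: int) -> float:
    """(DIC_SV − DIC_MSV) / (events × electrodes); positive favours MSV."""
    if n_events <= 0 or n_electrodes <= 0:
        raise ValueError("counts must be positive")
    return (dic_sv - dic_msv) / (n_events * n_electrodes)


def dic_probability_ratio(dic_a: float, dic_b: float) -> float:
    """Heuristic exp(ΔDIC/2)-style evidence ratio of model A over model B.

    This is an informal reading of DIC differences (analogous to Akaike
    weights), not a Bayes factor; treat it as descriptive only.
    """
    return float(np.exp((dic_b - dic_a) / 2.0))
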