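"""Scikit-learn style estimator around the thresholding pipeline.

``MultilevelThresholder`` is transform-shaped: ``fit`` searches for the
threshold values on each channel of the input image (RSA-Gbest by default,
or the exhaustive oracle), ``transform`` maps an image to its class-mean
reconstruction.  It composes with sklearn tooling via ``get_params`` /
``set_params`` and exposes fitted state with trailing-underscore names.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import metrics as qm
from .histograms import CHANNEL_NAMES, ChannelHistogram, image_histograms, split_channels, validate_image
from .objectives import ThresholdVector, exhaustive_search, score
from .rsa import OptimizerConfig, optimize


class MultilevelThresholder(BaseEstimator, TransformerMixin):
    """Multilevel image thresholding via RSA-Gbest or exhaustive search.

    Parameters
    ----------
    n_thresholds : int, default=2
        Number of thresholds K (the image is split into K+1 classes).
    objective : {"otsu", "kapur"}, default="otsu"
        Between-class variance or entropy criterion (both maximized).
    method : {"rsa", "exhaustive"}, default="rsa"
        Stochastic search or brute-force enumeration (K ≤ 3 at 256 levels).
    population, iterations, beta, alpha, epsilon, w_max, w_min, c1, c2 :
        RSA-Gbest tunables; see :class:`rsathresh.rsa.OptimizerConfig`.
    random_state : int or None
        Seed for the stochastic search.

    Attributes
    ----------
    thresholds_ : list of ThresholdVector, one per channel
    scores_ : list of float, objective value per channel
    traces_ : list of OptimizerTrace (empty for exhaustive)
    channel_names_ : list of str

    Examples
    --------
    >>> from rsathresh.synthetic import gaussian_mixture_image, MixtureSpec
    >>> img = gaussian_mixture_image(
    ...     MixtureSpec(((64, 5, 0.5), (192, 5, 0.5)), (64, 64), seed=0))
    >>> est = MultilevelThresholder(n_thresholds=1, random_state=0).fit(img)
    >>> seg = est.transform(img)
    """

    def __init__(
        self,
        n_thresholds: int = 2,
        objective: str = "otsu",
        method: str = "rsa",
        population: int = 25,
        iterations: int = 100,
        beta: float = 0.1,
        alpha: float = 0.1,
        epsilon: float = 1e-10,
        w_max: float = 0.9,
        w_min: float = 0.2,
        c1: float = 2.0,
        c2: float = 2.0,
        random_state: int | None = None,
    ):
        self.n_thresholds = n_thresholds
        self.objective = objective
        self.method = method
        self.population = population
        self.iterations = iterations
        self.beta = beta
        self.alpha = alpha
        self.epsilon = epsilon
        self.w_max = w_max
        self.w_min = w_min
        self.c1 = c1
        self.c2 = c2
        self.random_state = random_state

    def _config(self) -> OptimizerConfig:
        return OptimizerConfig(
            population=self.population,
            iterations=self.iterations,
            beta=self.beta,
            alpha=self.alpha,
            epsilon=self.epsilon,
            w_max=self.w_max,
            w_min=self.w_min,
            c1=self.c1,
            c2=self.c2,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        """Search thresholds on each channel of the image ``X``."""
        if self.n_thresholds < 1:
            raise ValueError("n_thresholds must be ≥ 1")
        if self.method not in ("rsa", "exhaustive"):
            raise ValueError(f"unknown method {self.method!r}")
        img = validate_image(np.asarray(X))
        hists = image_histograms(img)
        self.channel_names_ = [h.channel for h in hists]
        self.thresholds_: list[ThresholdVector] = []
        self.scores_: list[float] = []
        self.traces_ = []
        for h in hists:
            tv, sc, trace = self._fit_histogram(h)
            self.thresholds_.append(tv)
            self.scores_.append(sc)
            if trace is not None:
                self.traces_.append(trace)
        return self

    def fit_histogram(self, hist: ChannelHistogram):
        """Fit directly on a precomputed histogram (single channel)."""
        self.channel_names_ = [hist.channel]
        tv, sc, trace = self._fit_histogram(hist)
        self.thresholds_ = [tv]
        self.scores_ = [sc]
        self.traces_ = [] if trace is None else [trace]
        return self

    def _fit_histogram(self, h: ChannelHistogram):
        if self.method == "exhaustive":
            tv, sc = exhaustive_search(h, self.n_thresholds, self.objective)
            return tv, sc, None
        return optimize(h, self.n_thresholds, self.objective, self._config())

    def transform(self, X) -> np.ndarray:
        """Class-mean reconstruction of ``X`` under the fitted thresholds."""
        self._check_fitted()
        img = validate_image(np.asarray(X))
        channels = split_channels(img)
        if len(channels) != len(self.thresholds_):
            raise ValueError(
                f"image has {len(channels)} channel(s) but the estimator was "
                f"fitted on {len(self.thresholds_)}"
            )
        recs = [
            qm.apply_thresholds(ch, tv).reconstruction
            for ch, tv in zip(channels, self.thresholds_)
        ]
        if len(recs) == 1:
            return recs[0]
        return np.stack(recs, axis=-1)

    def score(self, X, y=None) -> float:
        """Mean objective value of the fitted thresholds on ``X``."""
        self._check_fitted()
        hists = image_histograms(validate_image(np.asarray(X)))
        return float(
            np.mean([score(h, tv, self.objective) for h, tv in zip(hists, self.thresholds_)])
        )

    def quality(self, X) -> dict[str, float]:
        """RMSE/PSNR/SSIM of the reconstruction, averaged over channels."""
        self._check_fitted()
        img = validate_image(np.asarray(X))
        channels = split_channels(img)
        reports = [
            qm.evaluate_segmentation(ch, qm.apply_thresholds(ch, tv))
            for ch, tv in zip(channels, self.thresholds_)
        ]
        return {
            "rmse": float(np.mean([r.rmse for r in reports])),
            "psnr": float(np.mean([r.psnr for r in reports])),
            "ssim": float(np.mean([r.ssim for r in reports])),
        }

    def _check_fitted(self) -> None:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("this MultilevelThresholder instance is not fitted yet")


def threshold_image(
    img: np.ndarray,
    n_thresholds: int = 2,
    objective: str = "otsu",
    method: str = "rsa",
    random_state: int | None = None,
    **kwargs,
) -> MultilevelThresholder:
    """One-call convenience wrapper: fit a thresholder on an image."""
    return MultilevelThresholder(
        n_thresholds=n_thresholds,
        objective=objective,
        method=method,
        random_state=random_state,
        **kwargs,
    ).fit(img)
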