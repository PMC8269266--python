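"""Sloan neutral community model (NCM).

The model predicts a taxon's detection frequency across local communities
from its mean relative abundance in the metacommunity. With community size
N (reads per sample), immigration rate m, and detection limit d = 1/N, the
expected frequency of a taxon with mean relative abundance p is

    freq(p) = 1 - B(d; N*m*p, N*m*(1 - p))

where B is the regularized incomplete beta CDF. ``SloanNCM`` fits the single
free parameter Nm by least squares of observed occurrence frequencies on the
prediction, reports a generalized R^2, and partitions taxa against 95%
Wilson binomial bands around the fitted curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .errors import DegenerateFitError, InvalidArgumentError

__all__ = [
    "predict_frequency",
    "occurrence_probability",
    "SloanNCM",
    "NCMResults",
    "fit_ncm",
    "ncm_report",
]


def predict_frequency(Nm: float, p, d: float):
    """Expected occurrence frequency of a taxon under the neutral model.

    ``p`` may be a scalar or array of mean relative abundances in (0, 1);
    ``d`` is the detection limit (one read at the sampling depth).
    """
    p = np.asarray(p, dtype=float)
    if Nm <= 0:
        raise InvalidArgumentError("Nm must be > 0")
    if not (0 < d < 1):
        raise InvalidArgumentError("d must lie in (0, 1)")
    if ((p <= 0) | (p >= 1)).any():
        raise InvalidArgumentError("p must lie strictly in (0, 1)")
    out = stats.beta.sf(d, Nm * p, Nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


def occurrence_probability(Nm: float, p, N: float, detection: str = "exact"):
    """Probability a taxon is seen at least once in a sample of N reads.

    ``detection='exact'`` uses the beta-binomial marginal
    1 - B(a, b + N)/B(a, b) with a = Nm*p, b = Nm*(1-p): the chance of
    drawing zero reads of a taxon whose local relative abundance follows
    the neutral stationary Beta. ``detection='threshold'`` is the classical
    step approximation P(x > d) with d = 1/N, i.e. :func:`predict_frequency`.
    """
    if detection == "threshold":
        return predict_frequency(Nm, p, 1.0 / N)
    if detection != "exact":
        raise InvalidArgumentError(f"unknown detection mode {detection!r}")
    p = np.asarray(p, dtype=float)
    if Nm <= 0:
        raise InvalidArgumentError("Nm must be > 0")
    a = Nm * p
    b = Nm * (1.0 - p)
    log_p0 = gammaln(b + N) + gammaln(a + b) - gammaln(b) - gammaln(a + b + N)
    out = -np.expm1(log_p0)
    return float(out) if out.ndim == 0 else out


def _wilson_band(pred: np.ndarray, n: int, z: float = 1.959963985) -> tuple[np.ndarray, np.ndarray]:
    """95% Wilson score interval around a predicted frequency with n trials."""
    denom = 1.0 + z**2 / n
    center = (pred + z**2 / (2 * n)) / denom
    half = z * np.sqrt(pred * (1 - pred) / n + z**2 / (4 * n**2)) / denom
    return np.clip(center - half, 0, 1), np.clip(center + half, 0, 1)


@dataclass
class NCMResults:
    """Fit results: Nm, m, R^2, and the per-taxon frequency table."""

    Nm: float
    N: float
    d: float
    r2: float
    n_samples: int
    otu_table: pd.DataFrame = field(repr=False)  # p, freq, predicted, lower, upper, partition
    detection: str = "exact"

    @property
    def m(self) -> float:
        return self.Nm / self.N

    def partition_counts(self) -> dict[str, int]:
        vc = self.otu_table["partition"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("above", "within", "below")}

    def report(self) -> dict:
        rec = {
            "Nm": self.Nm,
            "m": self.m,
            "N": self.N,
            "d": self.d,
            "R2": self.r2,
            "n_samples": self.n_samples,
            "n_otus": int(len(self.otu_table)),
        }
        rec.update({f"n_{k}": v for k, v in self.partition_counts().items()})
        return rec

    def to_json(self) -> str:
        return json.dumps(self.report(), sort_keys=True)

    def summary(self) -> str:
        pc = self.partition_counts()
        lines = [
            "Sloan neutral community model fit",
            "=" * 38,
            f"samples                {self.n_samples:>10d}",
            f"taxa                   {len(self.otu_table):>10d}",
            f"reads per sample (N)   {self.N:>10.1f}",
            f"Nm                     {self.Nm:>10.2f}",
            f"immigration rate m     {self.m:>10.4f}",
            f"R-squared              {self.r2:>10.4f}",
            f"above / within / below {pc['above']:>5d} {pc['within']:>5d} {pc['below']:>5d}",
        ]
        return "\n".join(lines)


class SloanNCM:
    """Neutral community model bound to an OTU count table.

    Expects a rarefied table (equal column sums); pass ``N`` explicitly to
    override, in which case the mean column sum convention applies.
    """

    def __init__(self, counts: pd.DataFrame, N: float | None = None):
        if counts.shape[0] < 10:
            raise InvalidArgumentError("NCM fit needs at least 10 OTUs")
        totals = counts.sum(axis=0)
        if N is None:
            if totals.nunique() != 1:
                raise InvalidArgumentError(
                    "unequal column sums; rarefy first or pass N explicitly"
                )
            N = float(totals.iloc[0])
        self.counts = counts
        self.N = float(N)
        self.d = 1.0 / self.N
        rel = counts / totals
        self.p = rel.mean(axis=1).to_numpy(dtype=float)
        self.freq = (counts > 0).mean(axis=1).to_numpy(dtype=float)
        self.otu_ids = list(counts.index)
        self.n_samples = counts.shape[1]

    def fit(
        self,
        log10_bounds: tuple[float, float] = (-1.0, 7.0),
        detection: str = "exact",
    ) -> NCMResults:
        """Fit Nm by bounded 1-D least squares on log10(Nm).

        ``detection`` selects the occurrence model: the exact beta-binomial
        marginal (default; unbiased against read-resampled data) or the
        classical ``'threshold'`` step at d = 1/N.
        """
        keep = (self.p > 0) & (self.p < 1)
        if (self.freq[keep] >= 1.0).all():
            raise DegenerateFitError(
                "every taxon occurs in every sample; occurrence carries no signal"
            )
        p, freq = self.p[keep], self.freq[keep]
        ids = [o for o, k in zip(self.otu_ids, keep) if k]

        def sse(lx: float) -> float:
            pred = occurrence_probability(10.0**lx, p, self.N, detection)
            return float(((freq - pred) ** 2).sum())

        grid = np.linspace(*log10_bounds, 33)
        best = grid[int(np.argmin([sse(x) for x in grid]))]
        lo = max(log10_bounds[0], best - 0.5)
        hi = min(log10_bounds[1], best + 0.5)
        res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded")
        nm = float(10.0**res.x)

        pred = occurrence_probability(nm, p, self.N, detection)
        ss_res = float(((freq - pred) ** 2).sum())
        ss_tot = float(((freq - freq.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        lower, upper = _wilson_band(pred, self.n_samples)
        partition = np.where(freq > upper, "above", np.where(freq < lower, "below", "within"))
        table = pd.DataFrame(
            {
                "p": p,
                "freq": freq,
                "predicted": pred,
                "lower": lower,
                "upper": upper,
                "partition": partition,
            },
            index=pd.Index(ids, name="otu_id"),
        )
        return NCMResults(
            Nm=nm, N=self.N, d=self.d, r2=float(r2),
            n_samples=self.n_samples, otu_table=table, detection=detection,
        )


def fit_ncm(counts: pd.DataFrame, N: float | None = None) -> NCMResults:
    """Convenience wrapper: ``SloanNCM(counts).fit()``."""
    return SloanNCM(counts, N=N).fit()


def ncm_report(fit: NCMResults) -> dict:
    """Serializable summary record of a fit."""
    return fit.report()
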