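"""Core community-table operations.

Rarefaction to a fixed read depth, relative abundances, alpha diversity,
and the dominant / conditionally-rare / always-rare partition of taxa by
per-sample relative abundance (0.01% and 1% cutoffs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyOutputError, InvalidArgumentError

__all__ = [
    "rarefy",
    "relative_abundance",
    "classify_taxa",
    "alpha_diversity",
    "AbundanceClassification",
    "DOMINANT",
    "CONDITIONALLY_RARE",
    "ALWAYS_RARE",
]

DOMINANT = "dominant"
CONDITIONALLY_RARE = "conditionally_rare"
ALWAYS_RARE = "always_rare"


def rarefy(
    counts: pd.DataFrame,
    depth: int,
    seed: int | np.random.Generator | None = None,
    drop_below: bool = True,
) -> pd.DataFrame:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped when ``drop_below``
    (the count is reported via a warning), otherwise they raise. OTUs left
    with all-zero rows are removed. Deterministic for a fixed seed.
    """
    if depth < 1:
        raise InvalidArgumentError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    shallow = totals.index[totals < depth]
    if len(shallow) == len(counts.columns):
        raise EmptyOutputError(
            f"no sample reaches depth {depth} (max total {int(totals.max())})"
        )
    if len(shallow) > 0:
        if not drop_below:
            raise InvalidArgumentError(
                f"samples below depth {depth}: {list(shallow)}"
            )
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {depth}: {list(shallow)}",
            stacklevel=2,
        )
    kept = [c for c in counts.columns if c not in set(shallow)]
    out = {}
    for col in kept:
        vec = counts[col].to_numpy(dtype=np.int64)
        if totals[col] == depth:
            out[col] = vec
        else:
            out[col] = rng.multivariate_hypergeometric(vec, depth)
    res = pd.DataFrame(out, index=counts.index)
    res = res.loc[res.sum(axis=1) > 0]
    res.index.name = counts.index.name
    return res


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; columns sum to 1."""
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero) > 0:
        raise InvalidArgumentError(f"sample(s) with zero total reads: {list(zero)}")
    return counts / totals


@dataclass
class AbundanceClassification:
    """Per-OTU abundance-class labels with the cutoffs that produced them."""

    labels: pd.Series
    rare_cutoff: float = 1e-4
    dominant_cutoff: float = 1e-2

    def members(self, label: str) -> list:
        return list(self.labels.index[self.labels == label])

    def counts(self) -> dict[str, int]:
        return {
            k: int((self.labels == k).sum())
            for k in (DOMINANT, CONDITIONALLY_RARE, ALWAYS_RARE)
        }

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("class").rename_axis("otu_id").to_frame()


def classify_taxa(
    rel_abund: pd.DataFrame,
    rare_cutoff: float = 1e-4,
    dominant_cutoff: float = 1e-2,
) -> AbundanceClassification:
    """Partition OTUs into dominant / conditionally-rare / always-rare classes.

    An OTU is *dominant* if it reaches ``rare_cutoff`` (default 0.01%) in every
    sample or ``dominant_cutoff`` (default 1%) in at least one; *always rare*
    if it stays below ``rare_cutoff`` everywhere; *conditionally rare*
    otherwise. Absence counts as below the rare cutoff. Dominant takes
    precedence when an OTU reaches 1% somewhere yet dips below 0.01%
    elsewhere.
    """
    if not (0 < rare_cutoff < dominant_cutoff < 1):
        raise InvalidArgumentError(
            f"need 0 < rare_cutoff < dominant_cutoff < 1, got "
            f"({rare_cutoff}, {dominant_cutoff})"
        )
    mx = rel_abund.max(axis=1)
    mn = rel_abund.min(axis=1)
    labels = pd.Series(CONDITIONALLY_RARE, index=rel_abund.index, name="class")
    labels[(mn >= rare_cutoff) | (mx >= dominant_cutoff)] = DOMINANT
    labels[mx < rare_cutoff] = ALWAYS_RARE
    return AbundanceClassification(labels, rare_cutoff, dominant_cutoff)


def _chao1(vec: np.ndarray, bias_corrected: bool) -> float:
    s = int((vec > 0).sum())
    f1 = int((vec == 1).sum())
    f2 = int((vec == 2).sum())
    if bias_corrected:
        return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s + f1 * (f1 - 1) / 2.0
    return s + f1 * f1 / (2.0 * f2)


def alpha_diversity(counts: pd.DataFrame, bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample richness, Shannon H' (nats), Chao1, and Pielou evenness.

    Evenness J = H'/ln(S); reported as missing (NaN) for single-taxon samples.
    Chao1 uses the bias-corrected form S + F1(F1-1)/(2(F2+1)) by default.
    """
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise InvalidArgumentError("negative counts")
    if (arr.sum(axis=0) < 1).any():
        raise InvalidArgumentError("every sample needs at least one read")
    rows = []
    for j, sample in enumerate(counts.columns):
        vec = arr[:, j]
        present = vec[vec > 0].astype(float)
        p = present / present.sum()
        s = len(present)
        h = float(-(p * np.log(p)).sum())
        j_even = h / np.log(s) if s > 1 else np.nan
        rows.append((sample, s, h, _chao1(vec, bias_corrected), j_even))
    return pd.DataFrame(
        rows, columns=["sample_id", "richness", "shannon", "chao1", "evenness"]
    ).set_index("sample_id")
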