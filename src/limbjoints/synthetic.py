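"""Synthetic specimen-level extant samples matched to published summaries.

The comparative extant data (humans, *Pan*, *Gorilla*, *Pongo*, pooled
hylobatids) are published only as per-dimension mean ± SD with N. This
module generates specimen-level samples whose marginal moments match those
summaries, so the whole pipeline — per-specimen RLSI distributions, range
membership, allometric fits — runs without the raw museum file.

Model
-----
Joint dimensions are positive and analysed on the log scale, so marginals
default to log-normal, moment-matched per element:

    sigma_log^2 = ln(1 + (sd/mean)^2),   mu_log = ln(mean) - sigma_log^2 / 2

Within a specimen, log dimensions are equicorrelated with parameter
``rho`` (default 0.8): joint sizes co-vary strongly through body size. The
generator draws z_i = sqrt(rho)*u + sqrt(1-rho)*e_i with u, e_i iid standard
normal, giving exact pairwise log-scale correlation ``rho`` and exact
marginal moments in expectation. A truncated-normal option exists as a
sensitivity switch (raw-scale normal, redrawing specimens with any
non-positive value; its moments are approximate for large cv).

What this does not emulate: sexual dimorphism, ontogeny, genus structure
within pooled taxa, and any real inter-element covariance beyond a single
shared size factor.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .elements import ALL_ELEMENTS
from .measurements import JointDimensionSet, RatioSpec

logger = logging.getLogger(__name__)

__all__ = [
    "TaxonSummary",
    "TaxonSample",
    "SyntheticConfig",
    "generate_taxon_sample",
    "generate_all",
    "summarize_sample",
]


@dataclass(frozen=True)
class TaxonSummary:
    """Per-element mean (mm), SD (mm) and N for one extant taxon."""

    taxon: str
    stats: Mapping[str, tuple[float, float, int]]  # element -> (mean, sd, n)

    def __post_init__(self) -> None:
        object.__setattr__(self, "stats", dict(self.stats))
        bad = set(self.stats) - set(ALL_ELEMENTS)
        if bad:
            raise ValueError(f"{self.taxon}: unknown elements {sorted(bad)}")
        for code, (mean, sd, n) in self.stats.items():
            if mean <= 0 or sd < 0 or n < 1:
                raise ValueError(
                    f"{self.taxon}/{code}: invalid summary ({mean}, {sd}, {n})"
                )
            if sd > 0.5 * mean:
                # e.g. a printed SD larger than half the mean is not a
                # credible linear measurement dispersion
                logger.warning(
                    "%s/%s: implausible dispersion mean=%.1f sd=%.1f (cv=%.2f)",
                    self.taxon, code, mean, sd, sd / mean,
                )

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_ELEMENTS if c in self.stats)

    def max_n(self) -> int:
        return max(n for _, _, n in self.stats.values())


@dataclass(frozen=True)
class TaxonSample:
    """Specimen-level measurements for one taxon (rows = specimens)."""

    taxon: str
    data: pd.DataFrame  # columns = element codes, values in mm

    def __post_init__(self) -> None:
        bad = set(self.data.columns) - set(ALL_ELEMENTS)
        if bad:
            raise ValueError(f"{self.taxon}: unknown columns {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.data)

    def rlsi_values(self, spec: RatioSpec) -> np.ndarray:
        """Per-specimen RLSI under ``spec`` (vectorised log-mean contrast)."""
        missing = [c for c in (*spec.upper, *spec.lower) if c not in self.data]
        if missing:
            raise ValueError(f"{self.taxon}: sample lacks elements {missing}")
        logs = np.log(self.data.to_numpy(dtype=float))
        cols = {c: i for i, c in enumerate(self.data.columns)}
        up = logs[:, [cols[c] for c in spec.upper]].mean(axis=1)
        lo = logs[:, [cols[c] for c in spec.lower]].mean(axis=1)
        return up - lo

    def to_dimension_sets(self) -> list[JointDimensionSet]:
        out = []
        for i, (_, row) in enumerate(self.data.iterrows()):
            out.append(
                JointDimensionSet(
                    f"{self.taxon}-{i:05d}", self.taxon,
                    {c: float(v) for c, v in row.items() if pd.notna(v)},
                )
            )
        return out

    def content_hash(self) -> str:
        csv = self.data.to_csv(float_format="%.10g").encode()
        return hashlib.sha256(csv).hexdigest()[:16]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    rho is the pairwise log-scale inter-element correlation (0 <= rho < 1);
    n_per_taxon overrides the published Ns; distribution is ``lognormal``
    (default) or ``truncnorm``.
    """

    seed: int = 0
    rho: float = 0.8
    n_per_taxon: Mapping[str, int] = field(default_factory=dict)
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_per_taxon", dict(self.n_per_taxon))
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.distribution not in ("lognormal", "truncnorm"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if any(n < 2 for n in self.n_per_taxon.values()):
            raise ValueError("n_per_taxon counts must be >= 2")


def _equicorrelated_normals(rng: np.random.Generator, n: int, k: int,
                            rho: float) -> np.ndarray:
    shared = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, k))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise


def generate_taxon_sample(
    summary: TaxonSummary,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> TaxonSample:
    """Draw a specimen-level sample matching ``summary``'s moments.

    Deterministic for a fixed config seed. An element with sd = 0 yields a
    constant column (with a warning).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    elements = summary.elements
    n = config.n_per_taxon.get(summary.taxon, summary.max_n())
    means = np.array([summary.stats[c][0] for c in elements])
    sds = np.array([summary.stats[c][1] for c in elements])
    for c in elements:
        if summary.stats[c][1] == 0 and n > 1:
            logger.warning("%s/%s: sd=0, generating constant column",
                           summary.taxon, c)

    z = _equicorrelated_normals(rng, n, len(elements), config.rho)
    if config.distribution == "lognormal":
        cv2 = (sds / means) ** 2
        sigma = np.sqrt(np.log1p(cv2))
        mu = np.log(means) - sigma**2 / 2.0
        data = np.exp(mu + sigma * z)
    else:  # truncnorm: raw-scale normal, redraw rows with non-positive values
        data = means + sds * z
        for _ in range(100):
            bad = (data <= 0).any(axis=1)
            if not bad.any():
                break
            zbad = _equicorrelated_normals(rng, int(bad.sum()), len(elements),
                                           config.rho)
            data[bad] = means + sds * zbad
        else:
            raise RuntimeError(f"{summary.taxon}: truncation rejection failed")
    df = pd.DataFrame(data, columns=list(elements))
    return TaxonSample(summary.taxon, df)


def generate_all(
    summaries: Mapping[str, TaxonSummary],
    config: SyntheticConfig,
) -> dict[str, TaxonSample]:
    """Generate every taxon from one seed, with per-taxon child streams.

    Child streams are spawned from the config seed in sorted-taxon order, so
    each taxon's sample is invariant to which other taxa are requested.
    """
    taxa = sorted(summaries)
    seqs = np.random.SeedSequence(config.seed).spawn(len(taxa))
    return {
        taxon: generate_taxon_sample(
            summaries[taxon], config, rng=np.random.default_rng(seq)
        )
        for taxon, seq in zip(taxa, seqs)
    }


def summarize_sample(sample: TaxonSample) -> TaxonSummary:
    """Per-element mean, SD (n-1 denominator) and non-missing count."""
    if sample.n == 0:
        raise ValueError(f"{sample.taxon}: empty sample")
    stats = {}
    for c in sample.data.columns:
        col = sample.data[c].dropna()
        stats[c] = (
            float(col.mean()),
            float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            int(len(col)),
        )
    return TaxonSummary(sample.taxon, stats)
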