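"""Reference-based taxon assignment from (ER, hilum angle).

Eccentricity ratio and hilum angle are the two characters that separate
the reference taxa cleanly (length and width distributions overlap), so
the assignment score is built on exactly this pair.  For each taxon a
product-Gaussian kernel density estimate is fitted on the longest-20%
stratum of its reference assemblage; a query granule receives posterior
probabilities proportional to the taxon densities under a uniform prior,
and is called only when the top posterior clears a confidence threshold,
otherwise "indeterminate".  Qualitative character frequencies are carried
alongside the model for reporting but do not enter the likelihood.

This scoring layer is a deliberately minimal operationalisation of
taxonomic assignment on top of the measurement core; the measurement and
comparison modules stand alone without it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import InsufficientDataError, StarchMorphError
from .geometry import GranuleMeasurement
from .stats import _stratum_stats, ks_two_sample, longest_subsample
from .synth import GranuleRecord

INDETERMINATE = "indeterminate"
_LOG_2PI = float(np.log(2.0 * np.pi))


def _silverman_bandwidths(pts: np.ndarray) -> np.ndarray:
    """Per-dimension Silverman bandwidths, h_d = sigma_d * n^(-1/(d+4))."""
    n, d = pts.shape
    sig = pts.std(axis=0, ddof=1)
    factor = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))
    return factor * sig


@dataclass
class ReferenceModel:
    """Per-taxon KDE over (ER, hilum angle) plus character frequencies."""

    taxa: list[str]
    points: dict[str, np.ndarray]           # taxon -> (n, 2) training array
    bandwidths: dict[str, np.ndarray]       # taxon -> (2,) positive scalars
    char_freqs: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise StarchMorphError("reference model needs >= 2 taxa")
        for t in self.taxa:
            if np.any(np.asarray(self.bandwidths[t]) <= 0):
                raise StarchMorphError(f"non-positive bandwidth for {t!r}")

    def log_density(self, taxon: str, xy: np.ndarray) -> np.ndarray:
        """Log KDE density of points ``xy`` (m, 2) under one taxon."""
        pts = self.points[taxon]
        h = np.asarray(self.bandwidths[taxon], dtype=float)
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        z = (xy[:, None, :] - pts[None, :, :]) / h    # (m, n, 2)
        log_kernel = -0.5 * np.sum(z * z, axis=2) - np.sum(np.log(h)) - _LOG_2PI
        return logsumexp(log_kernel, axis=1) - np.log(len(pts))

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {"taxa": self.taxa,
                "points": {t: self.points[t].tolist() for t in self.taxa},
                "bandwidths": {t: np.asarray(self.bandwidths[t]).tolist()
                               for t in self.taxa},
                "char_freqs": self.char_freqs}

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModel":
        return cls(taxa=list(d["taxa"]),
                   points={t: np.asarray(v, dtype=float)
                           for t, v in d["points"].items()},
                   bandwidths={t: np.asarray(v, dtype=float)
                               for t, v in d["bandwidths"].items()},
                   char_freqs=d.get("char_freqs", {}))

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class TaxonAssignment:
    """Per-granule assignment: log-densities, posteriors and the call."""

    granule_id: str
    log_density: dict
    posterior: dict
    call: str


def _features(m: GranuleMeasurement) -> np.ndarray:
    return np.array([m.eccentricity_ratio, m.hilum_angle])


def fit_reference(records_by_taxon: dict[str, Sequence[GranuleRecord]],
                  bandwidths: dict[str, Sequence[float]] | None = None,
                  fraction: float = 0.2,
                  min_per_taxon: int = 30) -> ReferenceModel:
    """Fit the per-taxon (ER, angle) KDE on the longest-``fraction`` stratum.

    Bandwidths follow Silverman's rule per dimension unless overridden.
    Deterministic: refitting identical data yields an identical model.
    """
    taxa = sorted(records_by_taxon)
    points, bws, chars = {}, {}, {}
    for t in taxa:
        sub = longest_subsample(list(records_by_taxon[t]), fraction)
        if len(sub) < min_per_taxon:
            raise InsufficientDataError(
                f"taxon {t!r}: only {len(sub)} granules in the "
                f"{fraction:.0%} stratum; need >= {min_per_taxon}")
        pts = np.array([_features(r.measurement) for r in sub])
        points[t] = pts
        bws[t] = (np.asarray(bandwidths[t], dtype=float)
                  if bandwidths is not None else _silverman_bandwidths(pts))
        _, freqs = _stratum_stats(sub)
        chars[t] = freqs
    return ReferenceModel(taxa=taxa, points=points, bandwidths=bws,
                          char_freqs=chars)


def classify_granule(measurement: GranuleMeasurement, model: ReferenceModel,
                     threshold: float = 0.8,
                     granule_id: str = "") -> TaxonAssignment:
    """Posterior taxon probabilities for one granule (uniform prior).

    The call is the argmax taxon when its posterior reaches ``threshold``,
    else "indeterminate".
    """
    if model is None:
        raise StarchMorphError("no reference model provided")
    xy = _features(measurement)[None, :]
    logd = {t: float(model.log_density(t, xy)[0]) for t in model.taxa}
    vals = np.array([logd[t] for t in model.taxa])
    post = np.exp(vals - logsumexp(vals))
    posterior = {t: float(p) for t, p in zip(model.taxa, post)}
    best = model.taxa[int(np.argmax(post))]
    call = best if posterior[best] >= threshold else INDETERMINATE
    return TaxonAssignment(granule_id=granule_id, log_density=logd,
                           posterior=posterior, call=call)


def classify_assemblage(records: Sequence[GranuleRecord],
                        model: ReferenceModel,
                        threshold: float = 0.8) -> dict:
    """Assemblage-level report: vote fractions and KS distances.

    Returns per-taxon vote fractions (plus the indeterminate fraction)
    and, for ER and angle, the KS D between the assemblage and each
    taxon's reference training sample.  Reporting only — no hard call.
    """
    records = list(records)
    if len(records) < 5:
        raise InsufficientDataError(
            f"assemblage has {len(records)} granules; need >= 5")
    calls = [classify_granule(r.measurement, model, threshold, r.id).call
             for r in records]
    n = len(calls)
    votes = {t: calls.count(t) / n for t in model.taxa}
    votes[INDETERMINATE] = calls.count(INDETERMINATE) / n
    er = np.array([r.measurement.eccentricity_ratio for r in records])
    ang = np.array([r.measurement.hilum_angle for r in records])
    ks = {}
    for t in model.taxa:
        d_er, _ = ks_two_sample(er, model.points[t][:, 0])
        d_ang, _ = ks_two_sample(ang, model.points[t][:, 1])
        ks[t] = {"er": d_er, "angle": d_ang}
    return {"n": n, "votes": votes, "ks_distance": ks}
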