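"""Scoring, classification and probabilistic filtering of HMM hits.

Each profile-HMM hit against a genome carries a bit score that grows with
hit length, so raw scores (and e-values, which underflow to zero for long
strong hits) would bias retention by gene length. The adjusted score — bit
score divided by hit length, i.e. score per base — removes that bias and is
the quantity modelled here.

Hits are classed by what they overlap in the existing annotation:

* good      — overlaps a gene of the orthogroup whose HMM produced the hit,
* bad       — overlaps only genes of other orthogroups,
* candidate — overlaps no annotated gene (a potential missing gene).

Skew-t distributions are fitted separately to the good and bad adjusted
scores per species; the class priors are the observed good/bad proportions.
A candidate hit is retained when its posterior probability of being genuine,

    P(genuine | x) = P(x|genuine) P(genuine)
                     / (P(x|genuine) P(genuine) + P(x|mistake) P(mistake)),

strictly exceeds 1/2. When a species has too few hits of either class to fit,
hits from all other species are pooled and the model is fitted to the pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_io import Annotation
from .intervals import GenomicInterval
from .orthogroups import Orthogroup
from .skewt import SkewTFit, SkewTParams, fit_skew_t

logger = logging.getLogger(__name__)

GOOD = "good"
BAD = "bad"
CANDIDATE = "candidate"

_LOG_UNDERFLOW = -700.0


class HitParseError(ValueError):
    pass


class InsufficientHitsError(RuntimeError):
    """Raised when even pooled hit classes cannot support a score-model fit."""


@dataclass(frozen=True)
class HmmHit:
    """One HMM-vs-genome match in genome coordinates."""

    og_id: str
    location: GenomicInterval
    bit_score: float
    species: str | None = None

    @property
    def length(self) -> int:
        return self.location.length

    @property
    def adjusted_score(self) -> float:
        return self.bit_score / self.length


def parse_hmm_hits(
    path: str | Path, og_id: str, species: str | None = None
) -> list[HmmHit]:
    """Parse an nhmmer per-target table into HmmHit records.

    Alignment coordinates (columns 7-8) are 1-based inclusive with from > to
    on the minus strand; they are normalised to 0-based half-open intervals
    with start < end.
    """
    hits: list[HmmHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 15:
                raise HitParseError(
                    f"line {lineno}: expected >= 15 whitespace-separated columns, "
                    f"got {len(fields)}"
                )
            target = fields[0]
            try:
                alifrom = int(fields[6])
                alito = int(fields[7])
                strand = fields[11]
                score = float(fields[13])
            except ValueError as exc:
                raise HitParseError(f"line {lineno}: malformed numeric field") from exc
            if strand not in ("+", "-"):
                raise HitParseError(f"line {lineno}: bad strand {strand!r}")
            lo, hi = min(alifrom, alito), max(alifrom, alito)
            start, end = lo - 1, hi
            if end <= start:
                logger.warning("line %d: zero-length hit skipped", lineno)
                continue
            hits.append(
                HmmHit(og_id, GenomicInterval(target, start, end, strand), score, species)
            )
    return hits


def classify_hit(hit: HmmHit, annotation: Annotation, og: Orthogroup) -> str:
    """good / bad / candidate by overlap with the existing annotation.

    Overlap is strand-agnostic and requires at least one shared base with a
    CDS interval. A hit touching any annotated gene is never a candidate.
    """
    overlaps_own = False
    overlaps_other = False
    own = og.species_of(annotation.species)
    for gene in annotation:
        if gene.seq_id != hit.location.seq_id:
            continue
        if any(hit.location.overlaps(iv) for iv in gene.cds):
            if gene.gene_id in own:
                overlaps_own = True
            else:
                overlaps_other = True
        if overlaps_own:
            break
    if overlaps_own:
        return GOOD
    if overlaps_other:
        return BAD
    return CANDIDATE


@dataclass
class ScoreModel:
    """Fitted per-species score model: class densities plus class priors."""

    species: str
    good_dist: SkewTParams
    bad_dist: SkewTParams
    prior_genuine: float
    prior_mistake: float
    n_good: int
    n_bad: int
    pooled: bool = False
    good_fit: SkewTFit | None = field(default=None, repr=False)
    bad_fit: SkewTFit | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_genuine < 1.0):
            raise ValueError("prior_genuine must lie in (0, 1)")
        if abs(self.prior_genuine + self.prior_mistake - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")

    def summary(self) -> str:
        rows = [
            f"Score model for species {self.species}"
            + (" (pooled across other species)" if self.pooled else ""),
            f"  n_good = {self.n_good}, n_bad = {self.n_bad}",
            f"  P(genuine) = {self.prior_genuine:.4f}, "
            f"P(mistake) = {self.prior_mistake:.4f}",
        ]
        for label, dist in (("good", self.good_dist), ("bad", self.bad_dist)):
            rows.append(
                f"  {label:4s}: loc={dist.loc:.4f} scale={dist.scale:.4f} "
                f"shape={dist.shape:.3f} df={dist.df:.2f}"
            )
        return "\n".join(rows)


def fit_score_model(
    good_scores: Sequence[float],
    bad_scores: Sequence[float],
    min_n: int = 50,
    species: str = "",
) -> ScoreModel | None:
    """Fit skew-t models to the good and bad adjusted-score samples.

    Returns None (the insufficient-data signal) when either class has fewer
    than ``min_n`` samples; callers then fall back to ``pooled_score_model``.
    """
    good = np.asarray(good_scores, dtype=float)
    bad = np.asarray(bad_scores, dtype=float)
    if good.size < min_n or bad.size < min_n:
        return None
    good_fit = fit_skew_t(good)
    bad_fit = fit_skew_t(bad)
    prior_genuine = good.size / (good.size + bad.size)
    return ScoreModel(
        species=species,
        good_dist=good_fit.params,
        bad_dist=bad_fit.params,
        prior_genuine=prior_genuine,
        prior_mistake=1.0 - prior_genuine,
        n_good=int(good.size),
        n_bad=int(bad.size),
        good_fit=good_fit,
        bad_fit=bad_fit,
    )


def pooled_score_model(
    per_species_hits: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    target_species: str,
    min_n: int = 50,
) -> ScoreModel:
    """Aggregation fallback: fit on good/bad scores pooled from other species."""
    good: list[float] = []
    bad: list[float] = []
    for species, (g, b) in per_species_hits.items():
        if species == target_species:
            continue
        good.extend(g)
        bad.extend(b)
    model = fit_score_model(good, bad, min_n=min_n, species=target_species)
    if model is None:
        raise InsufficientHitsError(
            f"species {target_species}: pooled good/bad hits still below "
            f"min_n={min_n}; add more (or more closely related) species"
        )
    model.pooled = True
    return model


def posterior_genuine(x, model: ScoreModel):
    """Bayes posterior P(genuine | adjusted score x).

    Evaluated in log space; where both class densities underflow, the data
    carry no information at x and the prior is returned with a warning.
    """
    x_arr = np.asarray(x, dtype=float)
    lg = model.good_dist.logpdf(x_arr)
    lb = model.bad_dist.logpdf(x_arr)
    underflow = (lg < _LOG_UNDERFLOW) & (lb < _LOG_UNDERFLOW)
    if np.any(underflow):
        logger.warning(
            "both score densities underflow at %d point(s); using prior",
            int(np.sum(underflow)),
        )
    a = lg + np.log(model.prior_genuine)
    b = lb + np.log(model.prior_mistake)
    with np.errstate(over="ignore"):
        post = 1.0 / (1.0 + np.exp(b - a))
    post = np.where(underflow, model.prior_genuine, post)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(post)
    return post


def filter_candidates(
    candidates: Sequence[HmmHit], model: ScoreModel
) -> tuple[list[HmmHit], list[HmmHit]]:
    """Partition candidate hits by the posterior rule.

    A hit is retained iff P(genuine | adjusted score) strictly exceeds 1/2
    (a tie means the hit is not *more* likely genuine, so it is rejected).
    Input order is preserved in both partitions.
    """
    retained: list[HmmHit] = []
    rejected: list[HmmHit] = []
    for hit in candidates:
        if posterior_genuine(hit.adjusted_score, model) > 0.5:
            retained.append(hit)
        else:
            rejected.append(hit)
    return retained, rejected


def write_score_diagnostics(
    model: ScoreModel,
    good_scores: Sequence[float],
    bad_scores: Sequence[float],
    path: str | Path,
    n_bins: int = 50,
) -> None:
    """Plain-TSV diagnostic: score histograms plus fitted densities on a grid."""
    good = np.asarray(good_scores, dtype=float)
    bad = np.asarray(bad_scores, dtype=float)
    pooled = np.concatenate([good, bad]) if good.size + bad.size else np.array([0.0, 1.0])
    lo, hi = float(pooled.min()), float(pooled.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    good_hist, _ = np.histogram(good, bins=edges, density=True)
    bad_hist, _ = np.histogram(bad, bins=edges, density=True)
    with open(path, "w") as fh:
        fh.write(
            "score\tgood_hist_density\tbad_hist_density\t"
            "good_fitted_pdf\tbad_fitted_pdf\tposterior_genuine\n"
        )
        g_pdf = model.good_dist.pdf(centres)
        b_pdf = model.bad_dist.pdf(centres)
        post = posterior_genuine(centres, model)
        for i, c in enumerate(centres):
            fh.write(
                f"{c:.6g}\t{good_hist[i]:.6g}\t{bad_hist[i]:.6g}\t"
                f"{g_pdf[i]:.6g}\t{b_pdf[i]:.6g}\t{post[i]:.6g}\n"
            )


def split_scores_by_class(
    hits: Iterable[HmmHit],
    annotation: Annotation,
    orthogroups: Mapping[str, Orthogroup],
) -> tuple[list[float], list[float], list[HmmHit]]:
    """Classify hits and return (good scores, bad scores, candidate hits)."""
    good: list[float] = []
    bad: list[float] = []
    candidates: list[HmmHit] = []
    for hit in hits:
        og = orthogroups[hit.og_id]
        cls = classify_hit(hit, annotation, og)
        if cls == GOOD:
            good.append(hit.adjusted_score)
        elif cls == BAD:
            bad.append(hit.adjusted_score)
        else:
            candidates.append(hit)
    return good, bad, candidates
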