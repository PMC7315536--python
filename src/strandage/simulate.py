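"""Seeded generators for synthetic methylation data.

Two generators cover everything the toolbox consumes:

* ``simulate_reads`` draws per-strand methylation patterns under the
  stochastic-drift model: at donor age ``a`` each CpG site ``i`` of an
  amplicon is methylated independently with probability
  ``clip(slope_i * a + intercept_i, 0, 1)``.  This is the same generative
  model the single-read predictor inverts, so the round trip through
  fitting and prediction is the principal end-to-end check.

* ``simulate_study_collection`` builds multi-cohort beta matrices with
  planted age-linear CpGs, per-(study, CpG) baseline offsets emulating
  inter-study batch variation, and Gaussian measurement noise, for
  exercising the CpG screen and the linear clocks.

Reproducibility: one root seed; each donor / study gets an independent
substream derived from a stable CRC32 hash of its identifier, so a subset
of donors regenerates identically regardless of iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MethylationMatrix, ReadPatternSet, SampleMetadata
from .selection import StudyCollection
from .singleread import SiteAgeModel, _probability_matrix

__all__ = [
    "SimulationSpec",
    "PlantedCpG",
    "simulate_reads",
    "simulate_study_collection",
    "sample_site_models",
]


def _substream(root_seed: int, *labels: str) -> np.random.Generator:
    keys = [zlib.crc32(lbl.encode()) for lbl in labels]
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) % (2**31), *keys]))


@dataclass
class SimulationSpec:
    """Parameters of a per-strand pattern simulation.

    ``site_models`` fixes the per-site linear frequency functions; donor
    ages are in years and every donor receives ``reads_per_donor``
    independent strands.
    """

    site_models: list[SiteAgeModel]
    donor_ages: list[float]
    reads_per_donor: int = 1000
    seed: int = 0
    amplicon_id: str = "sim_amplicon"
    sample_prefix: str = "donor"

    def __post_init__(self) -> None:
        if self.reads_per_donor < 1:
            raise ValueError("reads_per_donor must be >= 1")
        if any(a < 0 for a in self.donor_ages):
            raise ValueError("donor ages must be non-negative")
        if not self.site_models:
            raise ValueError("at least one site model required")

    @property
    def n_sites(self) -> int:
        return len(self.site_models)


def sample_site_models(
    n_sites: int,
    slope_range: tuple[float, float] = (0.002, 0.008),
    intercept_range: tuple[float, float] = (0.1, 0.4),
    seed: int | np.random.Generator = 0,
    amplicon_id: str = "sim_amplicon",
) -> list[SiteAgeModel]:
    """Draw site models with uniform slopes and mid-range baselines.

    Defaults emulate a strongly age-associated amplicon: per-year frequency
    gains of 0.2-0.8 percentage points, baselines kept off the clip
    boundaries so the site stays informative across adulthood.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slopes = rng.uniform(*slope_range, n_sites)
    intercepts = rng.uniform(*intercept_range, n_sites)
    return [SiteAgeModel(amplicon_id, i + 1, float(s), float(b))
            for i, (s, b) in enumerate(zip(slopes, intercepts))]


def simulate_reads(spec: SimulationSpec) -> list[ReadPatternSet]:
    """Generate counted per-strand patterns for every donor in the spec.

    Sites are independent Bernoulli draws at the donor's clipped site
    probabilities; identical seeds give identical output.
    """
    sets = []
    for d, age in enumerate(spec.donor_ages):
        sample_id = f"{spec.sample_prefix}{d:03d}"
        rng = _substream(spec.seed, spec.amplicon_id, sample_id)
        p = _probability_matrix(spec.site_models, np.array([float(age)]))[0]
        draws = rng.random((spec.reads_per_donor, spec.n_sites)) < p
        patterns: dict[str, int] = {}
        for row in draws:
            s = "".join("1" if b else "0" for b in row)
            patterns[s] = patterns.get(s, 0) + 1
        sets.append(ReadPatternSet(sample_id, spec.amplicon_id, spec.n_sites, patterns))
    return sets


@dataclass(frozen=True)
class PlantedCpG:
    """An age-linear CpG planted into a simulated study collection."""

    slope: float      # beta change per year
    intercept: float  # beta at age 0
    noise_sd: float   # per-measurement Gaussian noise on the beta scale


def simulate_study_collection(
    n_studies: int = 7,
    n_samples: int = 100,
    n_cpgs: int = 2000,
    planted: Sequence[PlantedCpG] = (),
    study_offset_sd: float = 0.02,
    noise_sd: float = 0.05,
    age_range: tuple[float, float] = (0.0, 100.0),
    pediatric_skew: bool = False,
    seed: int = 0,
) -> tuple[StudyCollection, list[str]]:
    """Multi-cohort beta matrices with planted age-associated CpGs.

    Planted CpGs occupy the first ``len(planted)`` ids; the rest are
    age-independent with baseline drawn uniform in [0.1, 0.9] and noise
    ``noise_sd``.  Every (study, CpG) pair receives one baseline offset
    drawn N(0, study_offset_sd), emulating array batch effects.  Betas are
    clipped to [0, 1].  Ages are uniform over ``age_range`` (or log-uniform
    when ``pediatric_skew``, concentrating mass at young ages to exercise
    the log branch of the age transform).

    Returns the collection and the planted CpG ids.
    """
    if len(planted) > n_cpgs:
        raise ValueError("more planted CpGs than CpGs")
    cpg_ids = [f"cg{i:07d}" for i in range(n_cpgs)]
    planted_ids = cpg_ids[: len(planted)]

    base_rng = _substream(seed, "collection")
    null_baseline = base_rng.uniform(0.1, 0.9, n_cpgs - len(planted))

    studies = []
    for s in range(n_studies):
        study = f"study{s:02d}"
        rng = _substream(seed, "study", study)
        if pediatric_skew:
            lo, hi = max(age_range[0], 0.0) + 1.0, age_range[1] + 1.0
            ages = np.exp(rng.uniform(np.log(lo), np.log(hi), n_samples)) - 1.0
        else:
            ages = rng.uniform(*age_range, n_samples)
        offsets = rng.normal(0.0, study_offset_sd, n_cpgs)

        betas = np.empty((n_cpgs, n_samples))
        for j, pc in enumerate(planted):
            betas[j] = pc.slope * ages + pc.intercept + rng.normal(0, pc.noise_sd, n_samples)
        k = len(planted)
        betas[k:] = null_baseline[:, None] + rng.normal(
            0, noise_sd, (n_cpgs - k, n_samples))
        betas += offsets[:, None]
        betas = np.clip(betas, 0.0, 1.0)

        sample_ids = [f"{study}_s{i:03d}" for i in range(n_samples)]
        matrix = MethylationMatrix(pd.DataFrame(betas, index=cpg_ids, columns=sample_ids))
        meta = SampleMetadata(pd.DataFrame(
            {"age": ages, "study": study}, index=pd.Index(sample_ids, name="sample_id")))
        studies.append((matrix, meta))
    return StudyCollection(studies), planted_ids
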