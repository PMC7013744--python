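"""Configuration dataclasses for the extraction, selection and search stages.

The texture bank, the SVM evaluator and the genetic-algorithm wrapper each
carry a small configuration object.  Defaults follow common texture-analysis
practice (32 gray levels, unit offsets, the four principal directions) and
the search hyper-parameters used in the original four-setting ultrasound
study (population 500, 500 generations, crossover 0.65, mutation 0.03,
roulette selection, two-point crossover).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import yaml

#: Angles (degrees) of the four principal 2-D directions.
PRINCIPAL_ANGLES: Tuple[int, ...] = (0, 45, 90, 135)

# Laws 1-D convolution vectors: level, edge and spot.
LAWS_L5: Tuple[int, ...] = (1, 4, 6, 4, 1)
LAWS_E5: Tuple[int, ...] = (-1, -2, 0, 2, 1)
LAWS_S5: Tuple[int, ...] = (-1, 0, 2, 0, -1)


@dataclass
class MatrixFamilyConfig:
    """Parameters of the matrix-based texture families.

    Attributes
    ----------
    quant_levels : int
        Gray levels used for the co-occurrence, run-length, dependence and
        tone-difference matrices (the image is min–max re-binned first).
    glcm_distance, glcm_angles : int, tuple of int
        Offset length and direction set of the co-occurrence matrix.
    glrlm_directions : tuple of int
        Directions along which maximal runs are scanned.
    ngldm_distance, ngldm_tolerance : int
        Chebyshev neighbourhood radius and gray-level tolerance ``a`` of the
        neighbouring gray-level dependence matrix.
    ngtdm_distance : int
        Neighbourhood radius of the gray-tone difference matrix.
    laws_vectors : tuple of 3 length-5 tuples
        The (L5, E5, S5) vectors whose outer products form the 5x5 masks.
    wavelet, wavelet_mode : str
        Wavelet basis and boundary-extension mode of the one-level DWT.
    epsilon : float
        Guard added to denominators that may legitimately vanish.
    """

    quant_levels: int = 32
    glcm_distance: int = 1
    glcm_angles: Tuple[int, ...] = PRINCIPAL_ANGLES
    sfm_displacements: Tuple[Tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    glrlm_directions: Tuple[int, ...] = PRINCIPAL_ANGLES
    ngldm_distance: int = 1
    ngldm_tolerance: int = 0
    ngtdm_distance: int = 1
    laws_vectors: Tuple[Tuple[int, ...], Tuple[int, ...], Tuple[int, ...]] = (
        LAWS_L5,
        LAWS_E5,
        LAWS_S5,
    )
    wavelet: str = "haar"
    wavelet_mode: str = "symmetric"
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.quant_levels < 2 or self.quant_levels > 256:
            raise ValueError("quant_levels must be in [2, 256]")
        if min(self.glcm_distance, self.ngldm_distance, self.ngtdm_distance) < 1:
            raise ValueError("matrix distances must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for v in self.laws_vectors:
            if len(v) != 5:
                raise ValueError("laws vectors must have length 5")


@dataclass
class SVMConfig:
    """RBF support-vector machine and cross-validation settings.

    ``kernel_width`` is sigma^2 of exp(-||x-x'||^2 / (2 sigma^2)); ``"auto"``
    sets it to half the median squared pairwise distance of the training
    split.  Folds are stratified and seeded for reproducibility.
    """

    kernel_width: float | str = "auto"
    C: float = 1.0
    folds: int = 5
    fold_seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not (self.kernel_width == "auto" or float(self.kernel_width) > 0):
            raise ValueError("kernel_width must be positive or 'auto'")


@dataclass
class GAParams:
    """Genetic-algorithm hyper-parameters.

    Defaults are the study settings: population 500 evolved for 500
    generations, two-point crossover with probability 0.65, bit-flip
    mutation at rate 0.03, roulette-wheel selection.  ``cardinality`` pins
    the number of selected features (enforced by a repair operator); ``None``
    leaves subset size free.
    """

    population_size: int = 500
    generations: int = 500
    crossover_probability: float = 0.65
    mutation_rate: float = 0.03
    cardinality: Optional[int] = None
    elitism: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for p in (self.crossover_probability, self.mutation_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PipelineConfig:
    """End-to-end run settings: extraction, filtering, search, evaluation."""

    matrix: MatrixFamilyConfig = field(default_factory=MatrixFamilyConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    ga: GAParams = field(default_factory=GAParams)
    filter_top_n: int = 40
    filter_pool_floor: int = 5
    cardinalities: Tuple[int, ...] = (5, 10, 15)
    split_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        matrix = MatrixFamilyConfig(**_tupled(raw.pop("matrix", {})))
        svm = SVMConfig(**raw.pop("svm", {}))
        ga = GAParams(**raw.pop("ga", {}))
        if "cardinalities" in raw:
            raw["cardinalities"] = tuple(raw["cardinalities"])
        return cls(matrix=matrix, svm=svm, ga=ga, **raw)


def _tupled(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, list):
            out[k] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            out[k] = v
    return out
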