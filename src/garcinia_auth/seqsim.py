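"""Synthetic reference libraries evolved under the Kimura two-parameter model.

Sequences evolve along a star species tree: each species root sits
``inter_depth`` expected substitutions per site from a common uniform-random
ancestor, and each individual (or query) sits ``intra_depth`` from its
species root.  That is the simplest topology producing the intra- versus
interspecific distance structure that barcode-gap analysis summarizes; a
user-supplied species tree can replace the star for richer scenarios.

Branch lengths are in expected substitutions per site: with transition rate
``alpha = kappa / (kappa + 2)`` and transversion rate
``beta = 1 / (kappa + 2)`` the total leaving rate per site is one, so the
closed-form transition probabilities at time ``t`` are

    P(same)            = 1/4 + 1/4 e^(-4 beta t) + 1/2 e^(-2 (alpha+beta) t)
    P(transition)      = 1/4 + 1/4 e^(-4 beta t) - 1/2 e^(-2 (alpha+beta) t)
    P(each transversion) = 1/4 - 1/4 e^(-4 beta t)

No indels or among-site rate variation are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .barcode import SequenceRecord
from .errors import InvalidParameterError

__all__ = [
    "K2PParams", "LibrarySpec", "SimulatedLibrary",
    "k2p_transition_probs", "expected_p_distance", "evolve_sequence",
    "random_sequence", "simulate_reference_library", "simulate_queries",
    "truth_table_csv",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# transition partner of each base (A<->G, C<->T), by index into BASES
_TRANSITION = {0: 2, 1: 3, 2: 0, 3: 1}


@dataclass(frozen=True)
class K2PParams:
    """kappa = transition/transversion rate ratio; t = branch length."""

    kappa: float = 2.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise InvalidParameterError("kappa must be positive")
        if self.t < 0:
            raise InvalidParameterError("t must be >= 0")


def k2p_transition_probs(params: K2PParams) -> np.ndarray:
    """4x4 substitution probability matrix (rows/cols in ACGT order)."""
    kappa, t = params.kappa, params.t
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_tv = math.exp(-4.0 * beta * t)
    e_ts = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e_tv + 0.5 * e_ts
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv
    mat = np.full((4, 4), p_tv)
    for i in range(4):
        mat[i, i] = p_same
        mat[i, _TRANSITION[i]] = p_ts
    return mat


def expected_p_distance(params: K2PParams) -> float:
    """Expected proportion of differing sites after one branch of length t."""
    mat = k2p_transition_probs(params)
    return float(1.0 - mat[0, 0])


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def evolve_sequence(ancestor: str, params: K2PParams,
                    rng: np.random.Generator) -> str:
    """Evolve each site independently via the K2P transition matrix."""
    if any(ch not in _BASE_INDEX for ch in ancestor):
        raise InvalidParameterError("ancestor must contain only A, C, G, T")
    if params.t == 0:
        return ancestor
    mat = k2p_transition_probs(params)
    cumulative = np.cumsum(mat, axis=1)
    idx = np.fromiter((_BASE_INDEX[c] for c in ancestor), dtype=np.int64,
                      count=len(ancestor))
    draws = rng.random(len(ancestor))
    rows = cumulative[idx]  # (n, 4)
    new_idx = (draws[:, None] > rows).sum(axis=1)
    return "".join(BASES[i] for i in new_idx)


@dataclass(frozen=True)
class LibrarySpec:
    """Design of one synthetic reference library.

    Depths are per-branch: two individuals of a species are separated by an
    expected 2 x intra_depth substitutions per site, and individuals of two
    species by roughly 2 x (inter_depth + intra_depth).
    """

    n_species: int = 6
    n_individuals: int = 3
    seq_length: int = 600
    intra_depth: float = 0.005
    inter_depth: float = 0.08
    kappa: float = 2.0
    seed: int = 0
    marker: str = "sim"

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_individuals) < 1:
            raise InvalidParameterError("counts must be >= 1")
        if self.seq_length < 100:
            raise InvalidParameterError("seq_length must be >= 100")
        if not 0 <= self.intra_depth < self.inter_depth:
            raise InvalidParameterError("need 0 <= intra_depth < inter_depth")
        if not self.kappa > 0:
            raise InvalidParameterError("kappa must be positive")


@dataclass
class SimulatedLibrary:
    """Records plus full generating ground truth."""

    spec: LibrarySpec
    records: list[SequenceRecord]
    species_roots: dict[str, str]
    ancestor: str
    truth: pd.DataFrame = field(repr=False, default=None)


def _species_name(i: int) -> str:
    return f"species_{i + 1:02d}"


def simulate_reference_library(spec: LibrarySpec) -> SimulatedLibrary:
    """Star-tree library: species roots from one ancestor, individuals below."""
    rng = np.random.default_rng(spec.seed)
    ancestor = random_sequence(spec.seq_length, rng)
    inter = K2PParams(spec.kappa, spec.inter_depth)
    intra = K2PParams(spec.kappa, spec.intra_depth)
    species_roots: dict[str, str] = {}
    records: list[SequenceRecord] = []
    rows = []
    for s in range(spec.n_species):
        species = _species_name(s)
        root = evolve_sequence(ancestor, inter, rng)
        species_roots[species] = root
        for k in range(spec.n_individuals):
            seq = evolve_sequence(root, intra, rng)
            rid = f"sp{s + 1:02d}_ind{k + 1}"
            records.append(SequenceRecord(rid, seq, species, spec.marker))
            rows.append({"id": rid, "species": species,
                         "intra_depth": spec.intra_depth,
                         "inter_depth": spec.inter_depth,
                         "kappa": spec.kappa, "seed": spec.seed,
                         "role": "reference"})
    truth = pd.DataFrame(rows)
    return SimulatedLibrary(spec, records, species_roots, ancestor, truth)


def simulate_queries(library: SimulatedLibrary, n_queries: int,
                     seed: int) -> tuple[list[SequenceRecord], list[str]]:
    """Unlabeled queries drawn from the library's species roots.

    Each query evolves ``intra_depth`` from a uniformly chosen species root,
    i.e. it is a new conspecific individual whose true species is returned
    alongside.
    """
    if n_queries < 1:
        raise InvalidParameterError("n_queries must be >= 1")
    rng = np.random.default_rng(seed)
    intra = K2PParams(library.spec.kappa, library.spec.intra_depth)
    species_names = sorted(library.species_roots)
    queries, truths = [], []
    for i in range(n_queries):
        species = species_names[int(rng.integers(len(species_names)))]
        seq = evolve_sequence(library.species_roots[species], intra, rng)
        queries.append(SequenceRecord(f"query_{i + 1:03d}", seq, None,
                                      library.spec.marker))
        truths.append(species)
    return queries, truths


def truth_table_csv(library: SimulatedLibrary, path) -> None:
    library.truth.to_csv(path, index=False)
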