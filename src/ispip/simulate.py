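"""Synthetic benchmark generator.

Emulates the statistical shape of a real interface-prediction benchmark so
the whole pipeline can be exercised without third-party predictors or
structure downloads:

* proteins of 50-450 residues (the size range where docking-based scoring
  remains reliable), with a per-protein interface fraction drawn from a
  Beta distribution around a mean of 12% — interfaces are a small minority
  class;
* three predictor channels whose scores are label-conditional Beta draws
  (a "moderate" channel emits Beta(4,2) scores on interfacial residues and
  Beta(2,4) on the rest), coupled across channels through a Gaussian-copula
  latent factor with correlation ``rho`` — rho 0 gives the orthogonal
  predictors a consensus model thrives on, rho → 1 collapses them into
  redundancy;
* optional per-(protein, channel) failures that replace a channel's scores
  with label-independent noise on a fraction of proteins, emulating e.g. a
  template-based method facing a query with no usable structural
  neighbours.

Failure replacement uses its own random substream, so the same seed with
and without failures yields datasets identical everywhere except the failed
cells — the paired design needed for robustness experiments.

Surface-exposed residue counts have no geometric meaning here and are fixed
at a configurable fraction of the length (default 70%).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from math import lcm
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dockpred import PoseSet
from .structure import Atom, ResidueKey, StructureModel
from .table import ScoreTable

__all__ = [
    "PredictorSpec",
    "SyntheticConfig",
    "generate_dataset",
    "generate_interaction_dataset",
    "generate_toy_complex",
    "generate_pose_fixture",
]

import pandas as pd


@dataclass(frozen=True)
class PredictorSpec:
    """Label-conditional Beta score model for one predictor channel.

    ``pos``/``neg`` are (a, b) Beta shape parameters for interfacial and
    non-interfacial residues.  With signal, the positive-class distribution
    must stochastically dominate the negative one (mean(pos) > mean(neg));
    equal parameters give a channel with no signal at all.
    """

    pos: tuple[float, float] = (4.0, 2.0)
    neg: tuple[float, float] = (2.0, 4.0)

    def validate(self) -> None:
        for pair in (self.pos, self.neg):
            if min(pair) <= 0:
                raise ValueError(f"Beta parameters must be positive, got {pair}")


def _default_predictors() -> dict[str, PredictorSpec]:
    return {
        "template_based": PredictorSpec(),
        "template_free": PredictorSpec(),
        "docking": PredictorSpec(),
    }


@dataclass
class SyntheticConfig:
    n_proteins: int = 100
    length_range: tuple[int, int] = (50, 450)
    interface_fraction_mean: float = 0.12
    interface_fraction_concentration: float = 25.0
    predictors: dict[str, PredictorSpec] = field(default_factory=_default_predictors)
    rho: float = 0.0
    #: probability that a channel fails on a protein; scalar or per-channel map
    failure_prob: float | Mapping[str, float] = 0.0
    surface_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("need at least one protein")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length range")
        if not 0 < self.interface_fraction_mean < 1:
            raise ValueError("interface fraction mean must be in (0,1)")
        if self.interface_fraction_concentration <= 0:
            raise ValueError("interface fraction concentration must be positive")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0,1]")
        for name in self.predictors:
            self.predictors[name].validate()
            p = self._failure_prob(name)
            if not 0 <= p <= 1:
                raise ValueError("failure probability must be in [0,1]")
        if not 0 < self.surface_fraction <= 1:
            raise ValueError("surface fraction must be in (0,1]")

    def _failure_prob(self, name: str) -> float:
        if isinstance(self.failure_prob, Mapping):
            return float(self.failure_prob.get(name, 0.0))
        return float(self.failure_prob)


def _copula_uniforms(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """n × k uniforms whose columns share a Gaussian latent factor at
    pairwise correlation rho (rho=0: independent; rho=1: identical)."""
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, k))
    z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    return stats.norm.cdf(z)


def generate_dataset(
    config: SyntheticConfig | None = None, seed: int | None = None, **overrides
) -> tuple[ScoreTable, dict[str, int]]:
    """Draw a labelled synthetic score table plus surface counts R.

    Reproducible: the same config (incl. seed) yields byte-identical
    tables.  ``seed``/keyword overrides clone the config first.
    """
    config = config or SyntheticConfig()
    if seed is not None or overrides:
        config = replace(config, **({"seed": seed} if seed is not None else {}), **overrides)
    config.validate()

    rng = np.random.default_rng(config.seed)
    failure_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA11]))
    names = list(config.predictors)
    k = len(names)
    a_f = config.interface_fraction_mean * config.interface_fraction_concentration
    b_f = (1 - config.interface_fraction_mean) * config.interface_fraction_concentration

    frames = []
    surface: dict[str, int] = {}
    for p in range(config.n_proteins):
        pid = f"P{p:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        frac = float(rng.beta(a_f, b_f))
        labels = (rng.random(length) < frac).astype(int)
        u = _copula_uniforms(rng, length, k, config.rho)
        cols = {}
        prevalence = labels.mean() if length else 0.0
        for j, name in enumerate(names):
            spec = config.predictors[name]
            a = np.where(labels == 1, spec.pos[0], spec.neg[0])
            b = np.where(labels == 1, spec.pos[1], spec.neg[1])
            cols[name] = stats.beta.ppf(u[:, j], a, b)
        # failures replace whole (protein, channel) columns with label-free noise
        for name in names:
            if failure_rng.random() < config._failure_prob(name):
                spec = config.predictors[name]
                mix_pos = failure_rng.random(length) < prevalence
                a = np.where(mix_pos, spec.pos[0], spec.neg[0])
                b = np.where(mix_pos, spec.pos[1], spec.neg[1])
                cols[name] = failure_rng.beta(a, b)
        frame = pd.DataFrame(
            {
                "protein_id": pid,
                "chain": "A",
                "resnum": np.arange(1, length + 1),
                "icode": "",
                **{name: cols[name] for name in names},
                "label": labels,
            }
        )
        frames.append(frame)
        surface[pid] = max(1, round(config.surface_fraction * length))
    table = ScoreTable(pd.concat(frames, ignore_index=True), predictors=names)
    return table, surface


def generate_interaction_dataset(
    n_proteins: int = 25,
    length_range: tuple[int, int] = (150, 250),
    seed: int = 0,
    flip_prob: float = 0.05,
    surface_fraction: float = 0.7,
) -> tuple[ScoreTable, dict[str, int]]:
    """Dataset where the label is an XOR-style interaction of two channels.

    A residue is interfacial when exactly one of the first two channels
    scores above 0.5 (with a small label flip probability); the third
    channel is pure noise.  No linear or logistic combination of the raw
    scores can express this rule, while depth-limited trees can — a
    controlled nonlinearity for comparing model families.
    """
    rng = np.random.default_rng(seed)
    frames = []
    surface: dict[str, int] = {}
    for p in range(n_proteins):
        pid = f"X{p:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        x1, x2, x3 = rng.random(length), rng.random(length), rng.random(length)
        labels = ((x1 > 0.5) ^ (x2 > 0.5)).astype(int)
        flip = rng.random(length) < flip_prob
        labels[flip] = 1 - labels[flip]
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": pid,
                    "chain": "A",
                    "resnum": np.arange(1, length + 1),
                    "icode": "",
                    "template_based": x1,
                    "template_free": x2,
                    "docking": x3,
                    "label": labels,
                }
            )
        )
        surface[pid] = max(1, round(surface_fraction * length))
    table = ScoreTable(
        pd.concat(frames, ignore_index=True),
        predictors=["template_based", "template_free", "docking"],
    )
    return table, surface


def generate_toy_complex(
    n_query: int, n_interface: int, seed: int = 0
) -> tuple[StructureModel, dict[ResidueKey, int]]:
    """Two-chain pseudo-structure with a known interface.

    Chain A carries ``n_query`` single-atom residues spaced 8 Å along x;
    chain B places one partner atom 3.5 Å from each designated interface
    residue.  Every non-designated residue is > 6 Å from all partner atoms,
    so a 4.0 Å contact rule recovers exactly the designated set.
    """
    if n_interface > n_query:
        raise ValueError("cannot designate more interface residues than residues")
    if n_query < 1:
        raise ValueError("need at least one query residue")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n_query, size=n_interface, replace=False).tolist())
    atoms: list[Atom] = []
    labels: dict[ResidueKey, int] = {}
    spacing = 8.0
    for i in range(n_query):
        x = i * spacing
        atoms.append(Atom("A", i + 1, "", "ALA", "CA", "C", x, 0.0, 0.0))
        labels[ResidueKey("A", i + 1, "")] = int(i in chosen)
    for j, i in enumerate(sorted(chosen), start=1):
        # 3.5 Å offset perpendicular to the chain axis; neighbours sit at
        # sqrt(8² + 3.5²) ≈ 8.7 Å, safely past the 6 Å exclusion margin
        atoms.append(Atom("B", j, "", "GLY", "CA", "C", i * spacing, 3.5, 0.0))
    if not chosen:
        atoms.append(Atom("B", 1, "", "GLY", "CA", "C", -50.0, 50.0, 0.0))
    return StructureModel(atoms), labels


def generate_pose_fixture(
    query_residues: Sequence[ResidueKey],
    schedules: Mapping[str, Mapping[ResidueKey, float]],
    seed: int = 0,
    max_denominator: int = 2000,
) -> list[PoseSet]:
    """Pose sets whose empirical interface fractions equal the requested
    schedule exactly.

    For each partner the pose count is the least common denominator of its
    scheduled fractions (capped at ``max_denominator``), and each residue
    appears in the first ``fraction * poses`` poses.  ``seed`` shuffles
    pose order, which the aggregation must be invariant to.
    """
    rng = np.random.default_rng(seed)
    query = set(query_residues)
    out: list[PoseSet] = []
    for partner, sched in schedules.items():
        stray = set(sched) - query
        if stray:
            raise ValueError(f"schedule references unknown residues: {sorted(stray)[:3]}")
        fracs = {
            key: Fraction(f).limit_denominator(max_denominator) for key, f in sched.items()
        }
        for key, f in fracs.items():
            if not 0 <= f <= 1:
                raise ValueError(f"schedule fraction out of [0,1] for {key}")
        denom = lcm(1, *(f.denominator for f in fracs.values()))
        sets = []
        for pose_idx in range(denom):
            members = frozenset(
                key for key, f in fracs.items() if pose_idx < f.numerator * (denom // f.denominator)
            )
            sets.append(members)
        order = rng.permutation(denom)
        out.append(PoseSet(partner, [sets[i] for i in order]))
    return out
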