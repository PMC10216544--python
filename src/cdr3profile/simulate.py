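"""Synthetic TCR-beta CDR3 cohorts with known ground truth.

The generator emulates the statistical shape of the study cohort it stands
in for: 4 ARDS-like and 3 non-ARDS-like lung-fluid samples, 25–1560 unique
clones per sample, in-frame nucleotide junctions of 21–69 nt (multiples of
3; 30–66 for the non-ARDS-like group) beginning with a cysteine codon
(TGT/TGC) and ending with a phenylalanine codon (TTT/TTC), a configurable
nonproductive fraction realized by +/-1 nt frameshifts or internal stop
codons, and clone frequencies drawn from a symmetric Dirichlet and realized
as template counts by multinomial sampling.

The per-sample Dirichlet concentration is solved from a target Simpson
clonality c via E[sum p_i^2] = (alpha + 1) / (n alpha + 1) = c^2, which is
feasible whenever c > 1/sqrt(n).  The default preset pairs each sample size
with a target clonality in 0.04–0.24 so the cohort spans the evenness range
the analysis is meant to resolve.  A shared-clone plan plants identical
junctions across chosen samples (by default four sequences within three
same-group samples and one across groups), always productive, providing
exact ground truth for sharing detection.

Junction interiors are uniform stop-free codons; no V/D/J gene-segment
model is attempted — clone identity, abundance and frame are the only
features any downstream statistic here consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import Cohort, Group, Rearrangement, Repertoire
from .translate import translate_repertoire

_STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOP_CODONS
)
_START_CODONS = ("TGT", "TGC")   # conserved cysteine
_END_CODONS = ("TTT", "TTC")     # conserved phenylalanine


def alpha_for_clonality(n_clones: int, clonality: float) -> float:
    """Symmetric-Dirichlet concentration whose expected Simpson clonality
    matches the target: alpha = (1 - c^2) / (n c^2 - 1)."""
    c2 = clonality ** 2
    if n_clones * c2 <= 1.0:
        raise ValueError(
            f"target clonality {clonality} is below the uniform floor "
            f"1/sqrt({n_clones}) and cannot be met"
        )
    return (1.0 - c2) / (n_clones * c2 - 1.0)


@dataclass
class SampleSpec:
    sample_id: str
    group: Group
    n_clones: int
    alpha: float | None = None
    target_clonality: float | None = None
    length_range: tuple[int, int] = (21, 69)
    depth: int | None = None
    #: "dirichlet" (symmetric, concentration alpha) or "powerlaw"
    #: (p_i proportional to rank^-alpha, ranks assigned randomly) — the
    #: heavy-tailed alternative for realistic expanded repertoires
    freq_model: str = "dirichlet"

    def resolved_alpha(self) -> float:
        if self.alpha is not None:
            return self.alpha
        if self.target_clonality is not None:
            return alpha_for_clonality(self.n_clones, self.target_clonality)
        return 1.0


def default_sample_specs() -> list[SampleSpec]:
    """The default 7-sample preset: sizes and target clonalities spanning
    the study conditions (sizes 25–1560, clonality 0.04–0.24; ARDS-like
    junction lengths 21–69 nt, non-ARDS-like 30–66 nt)."""
    ards = [("111", 1560, 0.095), ("176", 56, 0.144),
            ("186", 1485, 0.0406), ("251", 202, 0.2336)]
    non = [("158", 25, 0.2082), ("162", 118, 0.1951), ("163", 169, 0.111)]
    specs = [
        SampleSpec(sid, Group.ARDS, n, target_clonality=c,
                   length_range=(21, 69))
        for sid, n, c in ards
    ] + [
        SampleSpec(sid, Group.NON_ARDS, n, target_clonality=c,
                   length_range=(30, 66))
        for sid, n, c in non
    ]
    return specs


@dataclass
class SimulationConfig:
    seed: int
    samples: list[SampleSpec] = field(default_factory=default_sample_specs)
    nonproductive_fraction: float = 0.1
    depth_factor: int = 25
    #: list of (sequence count, sample subset) to plant as shared clones
    shared_plan: list[tuple[int, tuple[str, ...]]] = field(
        default_factory=lambda: [(4, ("111", "186", "251")), (1, ("186", "163"))]
    )
    shared_length_nt: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonproductive_fraction < 1.0:
            raise ValueError("nonproductive_fraction must be in [0, 1)")
        if self.shared_length_nt % 3:
            raise ValueError("shared_length_nt must be a multiple of 3")
        ids = {s.sample_id for s in self.samples}
        for count, subset in self.shared_plan:
            unknown = set(subset) - ids
            if unknown:
                raise ValueError(f"shared plan names unknown samples {unknown}")
        for s in self.samples:
            lo, hi = s.length_range
            if lo % 3 or hi % 3 or lo > hi or lo < 9:
                raise ValueError(
                    f"sample {s.sample_id}: length bounds {s.length_range} must "
                    "be multiples of 3, ordered, and >= 9"
                )
            planted = sum(c for c, subset in self.shared_plan
                          if s.sample_id in subset)
            budget = s.n_clones - planted
            if budget <= 0:
                raise ValueError(
                    f"sample {s.sample_id}: shared plan ({planted} clones) "
                    f"exceeds the clone budget ({s.n_clones})"
                )
            if round(self.nonproductive_fraction * s.n_clones) > budget:
                raise ValueError(
                    f"sample {s.sample_id}: nonproductive fraction leaves no "
                    "room for the planted (always productive) shared clones"
                )


def _random_junction(rng: np.random.Generator, length_nt: int) -> str:
    n_interior = length_nt // 3 - 2
    interior = "".join(
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_interior)
    )
    start = _START_CODONS[rng.integers(0, 2)]
    end = _END_CODONS[rng.integers(0, 2)]
    return start + interior + end


def _translate(nt: str) -> str:
    return "".join(
        _CODON_AA[nt[i:i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3)
    )


_CODON_AA: dict[str, str] = {}


def _build_codon_map() -> None:
    from Bio.Seq import Seq
    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                codon = a + b + c
                _CODON_AA[codon] = str(Seq(codon).translate())


_build_codon_map()


def _unique_junction(rng, length_nt, used: set[str],
                     used_aa: set[str] | None = None) -> str:
    """Draw a junction unique at the nucleotide level and — when ``used_aa``
    is given — also at the amino acid level, so convergent recombination
    cannot create unplanned cross-sample sharing."""
    while True:
        j = _random_junction(rng, length_nt)
        if j in used:
            continue
        if used_aa is not None:
            aa = _translate(j)
            if aa in used_aa:
                continue
            used_aa.add(aa)
        used.add(j)
        return j


def _make_nonproductive(rng, junction: str, used: set[str]) -> str:
    """Break a junction: delete one internal base (frameshift) or replace
    an interior codon with a stop, avoiding collisions with known clones."""
    for _ in range(100):
        if rng.random() < 0.5 and len(junction) > 4:
            pos = int(rng.integers(1, len(junction) - 1))
            mutant = junction[:pos] + junction[pos + 1:]
        else:
            codon_idx = int(rng.integers(1, len(junction) // 3 - 1))
            stop = _STOP_CODONS[rng.integers(0, 3)]
            mutant = (junction[:3 * codon_idx] + stop
                      + junction[3 * (codon_idx + 1):])
        if mutant not in used:
            used.add(mutant)
            return mutant
    raise RuntimeError("could not generate a unique nonproductive junction")


def _plant_shared(config: SimulationConfig, rng) -> dict[str, list[str]]:
    """Generate the planted shared sequences; returns sample_id -> junctions."""
    used: set[str] = set()
    per_sample: dict[str, list[str]] = {s.sample_id: [] for s in config.samples}
    planted: list[tuple[str, tuple[str, ...]]] = []
    for count, subset in config.shared_plan:
        for _ in range(count):
            j = _unique_junction(rng, config.shared_length_nt, used)
            planted.append((j, subset))
            for sid in subset:
                per_sample[sid].append(j)
    config._planted = planted  # ground truth, read by simulate_cohort
    return per_sample


def simulate_repertoire(
    config: SimulationConfig,
    spec: SampleSpec,
    rng: np.random.Generator,
    planted: Sequence[str] = (),
    used: set[str] | None = None,
    used_aa: set[str] | None = None,
) -> tuple[Repertoire, dict]:
    """Generate one sample; returns (repertoire, ground truth).

    ``used``/``used_aa`` are shared uniqueness registries; when a cohort is
    generated they span samples, so the only cross-sample sharing (at either
    sequence level) is the planted plan.
    """
    n = spec.n_clones
    lo, hi = spec.length_range
    lengths_allowed = np.arange(lo, hi + 1, 3)
    used = set() if used is None else used
    used_aa = set() if used_aa is None else used_aa
    used.update(planted)
    used_aa.update(_translate(j) for j in planted)

    junctions = list(planted)
    for _ in range(n - len(planted)):
        L = int(lengths_allowed[rng.integers(0, len(lengths_allowed))])
        junctions.append(_unique_junction(rng, L, used, used_aa))

    n_bad = round(config.nonproductive_fraction * n)
    # planted shared clones sit at the front and are never broken
    candidates = np.arange(len(planted), n)
    bad_idx = set(rng.choice(candidates, size=n_bad, replace=False).tolist()) \
        if n_bad else set()
    for i in sorted(bad_idx):
        junctions[i] = _make_nonproductive(rng, junctions[i], used)

    alpha = spec.resolved_alpha()
    if spec.freq_model == "dirichlet":
        p = rng.dirichlet(np.full(n, alpha))
    elif spec.freq_model == "powerlaw":
        p = (np.arange(1, n + 1, dtype=float) ** -alpha)
        p /= p.sum()
        rng.shuffle(p)
    else:
        raise ValueError(f"unknown freq_model {spec.freq_model!r}")
    depth = spec.depth if spec.depth is not None else config.depth_factor * n
    if depth < n:
        raise ValueError(f"sample {spec.sample_id}: depth {depth} < n_clones {n}")
    # every clone keeps at least one template so the unique-clone count is n
    templates = 1 + rng.multinomial(depth - n, p)

    rep = Repertoire.from_rearrangements(
        spec.sample_id,
        (Rearrangement(cdr3_nt=j, templates=int(t), sample_id=spec.sample_id)
         for j, t in zip(junctions, templates)),
        group=spec.group,
    )
    translate_repertoire(rep)
    truth = {
        "sample_id": spec.sample_id,
        "group": spec.group.value,
        "alpha": alpha,
        "true_frequencies": p.tolist(),
        "nonproductive": [junctions[i] for i in sorted(bad_idx)],
        "planted_shared": list(planted),
    }
    return rep, truth


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, dict]:
    """Generate the full cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    planted_by_sample = _plant_shared(config, rng)
    used: set[str] = set()
    used_aa: set[str] = set()
    repertoires, truths = [], {}
    for spec in config.samples:
        rep, truth = simulate_repertoire(
            config, spec, rng, planted=planted_by_sample[spec.sample_id],
            used=used, used_aa=used_aa,
        )
        repertoires.append(rep)
        truths[spec.sample_id] = truth
    cohort = Cohort(repertoires=repertoires,
                    provenance=f"synthetic cohort, seed={config.seed}")
    truth = {
        "seed": config.seed,
        "samples": truths,
        "planted_shared": [
            {"cdr3_nt": j, "samples": list(subset)}
            for j, subset in config._planted
        ],
    }
    return cohort, truth


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
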