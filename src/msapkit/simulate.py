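"""Synthetic-data generators with recorded ground truth.

Three generators cover every input the pipeline consumes:

* :func:`simulate_band_matrix` — MSAP presence/absence matrices. Each locus
  holds a latent methylation state in the control condition, transitions to
  a stress state via a 4x4 row-stochastic matrix, and each state emits an
  (EH, EM) digest pair deterministically; gel-scoring error then flips each
  digest call independently with a small probability (scoring errors are
  digest-specific, not locus-specific).
* :func:`simulate_bisulfite_reads` — bisulfite-converted top-strand reads
  from per-context methylation probabilities and a conversion rate.
* :func:`simulate_ct_table` — qPCR Ct tables from true fold changes with
  Gaussian technical noise.

Every generator takes an integer seed, draws from a single
``numpy.random.default_rng`` stream, and records the generating truth so
recovery tests can compare estimates against it. The bundled default band
config is derived from the shipped rice shoot pattern counts (IR29), giving
a realistic shoot-like regime (control MSAP near 60%, roughly half the loci
unchanged under stress); it is a demonstration regime, not deposited data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .bisulfite import CONTEXTS, BisulfiteRead, ReferenceSeq, classify_context
from .ddct import CtRecord
from .errors import ConfigError, EmptyInputError
from .pattern_dynamics import PATTERN_CLASSES, PATTERN_GROUPS

__all__ = [
    "STATE_NAMES",
    "STATE_EMISSION",
    "PAIR_TO_STATE",
    "SimulationConfig",
    "config_from_pattern_counts",
    "default_band_config",
    "simulate_band_matrix",
    "expected_class_probs",
    "expected_group_probs",
    "simulate_bisulfite_reads",
    "simulate_ct_table",
]

STATE_NAMES = (
    "unmethylated",
    "hemimethylated_external",
    "full_internal_CG",
    "full_both",
)

# latent state -> (eh, em) digest emission; the inverse of band typing:
# the states produce band types I, II, III, IV respectively.
STATE_EMISSION: dict[str, tuple[int, int]] = {
    "unmethylated": (1, 1),
    "hemimethylated_external": (1, 0),
    "full_internal_CG": (0, 1),
    "full_both": (0, 0),
}

PAIR_TO_STATE = {v: k for k, v in STATE_EMISSION.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for an MSAP band matrix.

    Parameters
    ----------
    n_loci
        Number of CCGG loci to simulate.
    state_probs_control
        Probability of each latent state in the control condition, in
        :data:`STATE_NAMES` order; must sum to 1.
    transition_matrix
        4x4 row-stochastic matrix of control-state to stress-state
        transition probabilities.
    scoring_noise
        Probability that any single digest call is flipped by gel-scoring
        error, independently per call.
    seed
        RNG seed; the same seed reproduces the output bit-for-bit.
    """

    n_loci: int
    state_probs_control: tuple[float, ...]
    transition_matrix: tuple[tuple[float, ...], ...]
    scoring_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.state_probs_control, dtype=float)
        trans = np.asarray(self.transition_matrix, dtype=float)
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1) > 1e-9:
            raise ConfigError("state_probs_control must be a 4-simplex")
        if (trans.shape != (4, 4) or (trans < 0).any()
                or np.abs(trans.sum(axis=1) - 1).max() > 1e-9):
            raise ConfigError("transition_matrix must be 4x4 row-stochastic")
        if not 0 <= self.scoring_noise <= 1:
            raise ConfigError("scoring_noise must be in [0, 1]")

    @property
    def probs(self) -> np.ndarray:
        return np.asarray(self.state_probs_control, dtype=float)

    @property
    def trans(self) -> np.ndarray:
        return np.asarray(self.transition_matrix, dtype=float)


def config_from_pattern_counts(
    class_counts: Mapping[str, int],
    *,
    n_loci: int = 5000,
    scoring_noise: float = 0.02,
    seed: int = 0,
) -> SimulationConfig:
    """Build a config whose joint law matches observed pattern-class counts.

    Each class A-P fixes both the control and the stress digest pair, hence
    both latent states; the empirical 4x4 joint over (control state, stress
    state) is row-normalised into the transition matrix and its row margins
    become the control state probabilities.
    """
    joint = np.zeros((4, 4))
    for quad, klass in PATTERN_CLASSES.items():
        s = STATE_NAMES.index(PAIR_TO_STATE[quad[:2]])
        t = STATE_NAMES.index(PAIR_TO_STATE[quad[2:]])
        joint[s, t] += class_counts.get(klass, 0)
    total = joint.sum()
    if total == 0:
        raise ConfigError("pattern counts are all zero")
    margins = joint.sum(axis=1)
    trans = np.eye(4)  # identity rows for states never observed in control
    observed = margins > 0
    trans[observed] = joint[observed] / margins[observed, None]
    return SimulationConfig(
        n_loci=n_loci,
        state_probs_control=tuple(margins / total),
        transition_matrix=tuple(map(tuple, trans)),
        scoring_noise=scoring_noise,
        seed=seed,
    )


def default_band_config(n_loci: int = 5000, scoring_noise: float = 0.02,
                        seed: int = 0) -> SimulationConfig:
    """Shoot-like demonstration regime from the bundled IR29 shoot counts."""
    return config_from_pattern_counts(
        datasets.pattern_class_counts("IR29", "shoot"),
        n_loci=n_loci, scoring_noise=scoring_noise, seed=seed)


def simulate_band_matrix(
    config: SimulationConfig, sample: str = "sim"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a band matrix (long form) and its ground-truth table.

    Returns
    -------
    bands
        Long-form frame with columns locus_id, sample, condition, enzyme,
        present — one row per locus x {control, stress} x {EH, EM}.
    truth
        One row per locus: the latent control and stress states, the
        noiseless quad, and the observed (possibly flipped) quad.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    control_states = rng.choice(4, size=n, p=config.probs)
    stress_states = np.array([
        rng.choice(4, p=config.trans[s]) for s in control_states])

    emissions = np.array([STATE_EMISSION[s] for s in STATE_NAMES])
    true_quads = np.hstack([emissions[control_states], emissions[stress_states]])
    flips = rng.random(true_quads.shape) < config.scoring_noise
    observed = np.where(flips, 1 - true_quads, true_quads)

    locus_ids = [f"L{i:05d}" for i in range(n)]
    rows = []
    for cond_idx, condition in enumerate(("control", "stress")):
        for enz_idx, enzyme in enumerate(("EH", "EM")):
            col = 2 * cond_idx + enz_idx
            for i in range(n):
                rows.append((locus_ids[i], sample, condition, enzyme,
                             int(observed[i, col])))
    bands = pd.DataFrame(
        rows, columns=["locus_id", "sample", "condition", "enzyme", "present"])
    truth = pd.DataFrame({
        "locus_id": locus_ids,
        "control_state": [STATE_NAMES[s] for s in control_states],
        "stress_state": [STATE_NAMES[s] for s in stress_states],
        "true_quad": ["".join(map(str, q)) for q in true_quads],
        "observed_quad": ["".join(map(str, q)) for q in observed],
    })
    return bands, truth


def expected_class_probs(config: SimulationConfig) -> dict[str, float]:
    """Exact class probabilities implied by a config, by enumeration.

    Sums the (state pair -> quad) law over the 16-cell joint distribution,
    then pushes it through the per-call flip channel of the scoring noise.
    """
    eps = config.scoring_noise
    true_prob: dict[tuple[int, ...], float] = {}
    for s, t in itertools.product(range(4), repeat=2):
        quad = STATE_EMISSION[STATE_NAMES[s]] + STATE_EMISSION[STATE_NAMES[t]]
        true_prob[quad] = true_prob.get(quad, 0.0) + config.probs[s] * config.trans[s, t]

    class_probs = {k: 0.0 for k in "ABCDEFGHIJKLMNOP"}
    for obs in itertools.product((0, 1), repeat=4):
        p_obs = 0.0
        for quad, p in true_prob.items():
            n_flip = sum(o != q for o, q in zip(obs, quad))
            p_obs += p * eps ** n_flip * (1 - eps) ** (4 - n_flip)
        class_probs[PATTERN_CLASSES[obs]] += p_obs
    return class_probs


def expected_group_probs(config: SimulationConfig) -> dict[str, float]:
    """Exact no-change / demethylation / methylation probabilities."""
    groups = {"no_change": 0.0, "demethylation": 0.0, "methylation": 0.0}
    for klass, p in expected_class_probs(config).items():
        groups[PATTERN_GROUPS[klass]] += p
    return groups


def simulate_bisulfite_reads(
    ref: ReferenceSeq,
    p_cg: float,
    p_chg: float,
    p_chh: float,
    *,
    conversion_rate: float = 1.0,
    n_reads: int = 1,
    seed: int = 0,
    id_prefix: str = "read",
    sample: str = "sim",
    tissue: str = "shoot",
    condition: str = "control",
) -> tuple[list[BisulfiteRead], pd.DataFrame]:
    """Emit bisulfite-converted copies of a reference with known truth.

    Per read and per reference C: the site is methylated with its context
    probability (undefined-context Cs use the CHH rate); a methylated C is
    emitted as C; an unmethylated C converts to T with ``conversion_rate``
    and otherwise stays C (non-conversion error). Non-C bases are copied.

    Returns the reads and a truth frame with one row per (read, C position).
    """
    for name, p in (("p_cg", p_cg), ("p_chg", p_chg), ("p_chh", p_chh),
                    ("conversion_rate", conversion_rate)):
        if not 0 <= p <= 1:
            raise ConfigError(f"{name} must be in [0, 1], got {p}")
    c_positions = [i + 1 for i, b in enumerate(ref.seq) if b == "C"]
    if not c_positions:
        raise EmptyInputError(f"reference {ref.id!r} contains no cytosine")
    p_by_context = {"CG": p_cg, "CHG": p_chg, "CHH": p_chh, "undefined": p_chh}
    contexts = {pos: classify_context(ref, pos) for pos in c_positions}

    rng = np.random.default_rng(seed)
    reads: list[BisulfiteRead] = []
    truth_rows = []
    for r in range(n_reads):
        bases = list(ref.seq)
        read_id = f"{id_prefix}{r:03d}"
        for pos in c_positions:
            ctx = contexts[pos]
            methylated = rng.random() < p_by_context[ctx]
            if methylated:
                emitted = "C"
            else:
                emitted = "T" if rng.random() < conversion_rate else "C"
            bases[pos - 1] = emitted
            truth_rows.append((read_id, pos, ctx, methylated, emitted))
        reads.append(BisulfiteRead(
            id=read_id, seq="".join(bases),
            sample=sample, tissue=tissue, condition=condition))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "ref_pos", "context", "methylated", "emitted"])
    return reads, truth


def simulate_ct_table(
    genes: Sequence[str],
    samples: Sequence[str],
    true_folds: Mapping[tuple[str, str], float],
    *,
    reference_gene: str = "eEF1a",
    n_bio_reps: int = 2,
    n_tech_reps: int = 3,
    ct_noise_sd: float = 0.2,
    baseline_ct: float = 25.0,
    reference_ct: float = 20.0,
    seed: int = 0,
) -> list[CtRecord]:
    """Generate a qPCR Ct table realising given true fold changes.

    The reference gene sits at a constant baseline in both conditions; each
    target gene's stress Ct is offset by ``-log2(fold)`` relative to its
    control Ct (one extra fold of expression removes one cycle). Gaussian
    noise of ``ct_noise_sd`` cycles is added independently per technical
    replicate. ``true_folds`` maps (gene, sample) to the fold; missing keys
    default to 1.
    """
    for key, fold in true_folds.items():
        if fold <= 0:
            raise ConfigError(f"true fold for {key} must be positive, got {fold}")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for sample in samples:
        for gene in list(genes) + [reference_gene]:
            if gene == reference_gene:
                ct_control = ct_stress = reference_ct
            else:
                fold = true_folds.get((gene, sample), 1.0)
                ct_control = baseline_ct
                ct_stress = baseline_ct - float(np.log2(fold))
            for bio in range(1, n_bio_reps + 1):
                for cond, ct_mean in (("control", ct_control), ("stress", ct_stress)):
                    for tech in range(1, n_tech_reps + 1):
                        ct = ct_mean + rng.normal(0.0, ct_noise_sd)
                        records.append(CtRecord(
                            gene=gene, sample=sample, condition=cond,
                            bio_rep=bio, tech_rep=tech, ct=float(ct)))
    return records
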