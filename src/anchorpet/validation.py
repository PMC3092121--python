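"""Simulation-driven validation experiments for the breakpoint caller.

Two standard experiments, used both by the test suite and by the
reproduction script:

* `breakpoint_recovery_experiment` — replicate simulations of a reciprocal
  translocation pushed through the whole pipeline, measuring how far the
  called interval lands from the planted junction. Replicates are
  conditioned on a minimum number of junctional chromPETs (the evidence
  level the localization claim is about).

* `scattered_nocall_experiment` — the negative control: junctional chromPETs
  with uniformly scattered coordinates (emulating cross-sample contamination
  in a sample without the translocation, where junctional tags map all over
  both loci rather than piling up at a junction) must not produce a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import MappedTag, TargetLocus
from .breakpoints import CallStatus, CallThresholds, predict_all
from .junctions import prediction_distance
from .petcall import ChromPET, FragmentLengthModel, PetClass
from .pipeline import run_simulated_replicate
from .simulate import SimulationConfig

# The no-call emulation scatters tags over gene-scale mapping targets (a
# ~135-kb breakpoint-cluster-region gene and a ~175-kb partner gene): in a
# contaminated sample the junctional tags disperse over the full mapped loci.
SCATTER_LOCUS_LENGTHS = (135_000, 175_000)


@dataclass(frozen=True)
class RecoveryOutcome:
    """One replicate of the localization experiment."""

    seed: int
    n_junctional: int
    status_ab: CallStatus  # A->B orientation call on the small locus
    distance_ab: Optional[int]  # called interval vs planted junction, bp
    truth_within_tolerance: bool  # junction inside or within mean+2sd of call


def breakpoint_recovery_experiment(
    n_replicates: int,
    base_seed: int,
    config: Optional[SimulationConfig] = None,
    *,
    min_junctional: int = 10,
    thresholds: CallThresholds = CallThresholds(),
) -> list[RecoveryOutcome]:
    """Measure breakpoint-localization error over seeded replicates.

    Each replicate draws fresh 7-kb / 175-kb loci, plants one balanced
    reciprocal translocation at a random position (uniform, away from the
    locus edges), simulates `config.n_pairs` read pairs at the configured
    tumor fraction, runs the full pipeline, and records the
    prediction-to-truth distance of the A->B call on the small locus.
    Replicates are re-drawn (under a derived seed) until they contain at
    least `min_junctional` junctional chromPETs.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(base_seed)
    outcomes = []
    for i in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        len_a, len_b = config.locus_lengths
        margin_a = max(1000, config.frag_mean + 3 * config.frag_sd)
        margin_b = max(1000, config.frag_mean + 3 * config.frag_sd)
        rep_config = SimulationConfig(
            **{
                **config.__dict__,
                "breakpoint_a": int(rng.integers(margin_a, len_a - margin_a + 1)),
                "breakpoint_b": int(rng.integers(margin_b, len_b - margin_b + 1)),
                "seed": rep_seed,
            }
        )
        result = run_simulated_replicate(
            rep_config, rep_seed, min_junctional=min_junctional,
            thresholds=thresholds,
        )
        truth = result.sample.truth
        locus_a, locus_b = rep_config.locus_names
        pred = result.run.predictions[rep_config.sample_id][
            f"{locus_a}->{locus_b}"
        ][locus_a]
        model = result.run.model
        if pred.status is CallStatus.CALLED:
            junction = (
                truth.junction_ab.five_last_retained,
                truth.junction_ab.five_last_retained + 1,
            )
            distance = prediction_distance(pred.interval, junction)
            within = distance <= model.mean + 2 * model.sd
        else:
            distance = None
            within = False
        outcomes.append(
            RecoveryOutcome(
                seed=rep_seed,
                n_junctional=result.n_junctional,
                status_ab=pred.status,
                distance_ab=distance,
                truth_within_tolerance=within,
            )
        )
    return outcomes


def recovery_distances(
    outcomes: Sequence[RecoveryOutcome], no_call_penalty: float = np.inf
) -> np.ndarray:
    """Per-replicate distances, with no-calls counted as `no_call_penalty`."""
    return np.array(
        [
            o.distance_ab if o.distance_ab is not None else no_call_penalty
            for o in outcomes
        ],
        dtype=float,
    )


@dataclass(frozen=True)
class ScatterOutcome:
    seed: int
    statuses: tuple[CallStatus, ...]  # all orientation x locus predictions

    @property
    def all_no_call(self) -> bool:
        return all(s is CallStatus.NO_CALL for s in self.statuses)

    @property
    def any_called(self) -> bool:
        return any(s is CallStatus.CALLED for s in self.statuses)


def scattered_nocall_experiment(
    n_replicates: int,
    base_seed: int,
    *,
    n_pets: int = 10,
    locus_lengths: tuple[int, int] = SCATTER_LOCUS_LENGTHS,
    tag_length: int = 38,
    model: FragmentLengthModel = FragmentLengthModel(mean=500, sd=50, n=0),
    thresholds: CallThresholds = CallThresholds(),
) -> list[ScatterOutcome]:
    """Dispersed junctional chromPETs must yield no breakpoint call.

    Each replicate fabricates `n_pets` junctional chromPETs whose tag
    coordinates are uniform over gene-scale loci and whose fusion
    orientations are random, then runs the voting and calling stages under
    the given fragment model and thresholds.
    """
    rng = np.random.default_rng(base_seed)
    len_a, len_b = locus_lengths
    loci = [
        TargetLocus("locusA", "A" * len_a),
        TargetLocus("locusB", "A" * len_b),
    ]
    outcomes = []
    for i in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        pets = []
        for j in range(n_pets):
            start_a = int(rep_rng.integers(1, len_a - tag_length + 2))
            start_b = int(rep_rng.integers(1, len_b - tag_length + 2))
            # FR-consistent junctional pair: the 5'-donor tag is +, mate -
            a_plus = bool(rep_rng.integers(0, 2))
            tag_a = MappedTag(
                f"scatter{j}", 1, "locusA", start_a, start_a + tag_length - 1,
                "+" if a_plus else "-",
            )
            tag_b = MappedTag(
                f"scatter{j}", 2, "locusB", start_b, start_b + tag_length - 1,
                "-" if a_plus else "+",
            )
            pets.append(
                ChromPET(f"scatter{j}", tag_a, tag_b, "scatter", PetClass.JUNCTIONAL)
            )
        predictions = predict_all(pets, loci, model, thresholds)
        statuses = tuple(
            pred.status
            for by_locus in predictions.values()
            for pred in by_locus.values()
        )
        outcomes.append(ScatterOutcome(rep_seed, statuses))
    return outcomes
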