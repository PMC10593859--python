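"""Synthetic longitudinal vaccine-study data for end-to-end testing.

The generator emulates the structure of a two-dose-arm vaccine
reactogenicity study: subjects sampled at baseline (D1), one day
post-prime (D2), one week post-prime (D8) and optionally one day
post-boost (D58); pathway activation that peaks at D2, is resolved by D8,
and is weaker in the lower-dose arm; a SomaScan-style serum panel with a
couple of patient samples carrying a strong coagulation/platelet signal
at days 15-19; and plate calibrator/QC replicate tables for the QC gates.

Counts follow a negative-binomial model on the log2 scale: per-feature
baseline + subject offset + arm-and-timepoint effect for members of
activated sets. RFU intensities are log-normal. Every draw is
deterministic for a fixed seed (numpy PCG64 via ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleTable,
    ValidationError,
)

#: Effects are ``{set_name: {arm: {timepoint: log2 effect}}}``.
EffectMap = dict[str, dict[str, dict[str, float]]]


@dataclass
class SimulationDesign:
    """Parameters of one simulated study.

    Dose monotonicity (the lower-dose arm's effect never exceeds the
    higher-dose arm's) and resolution by D8 (all D8 effects zero) are
    enforced at construction, mirroring the kinetics the pipeline is
    meant to detect.
    """

    n_features: int = 2000
    n_subjects_per_arm: int = 10
    arms: tuple[str, ...] = ("ad26_5e10", "ad26_1e11")
    timepoints: tuple[str, ...] = ("D1", "D2", "D8")
    activated_sets: EffectMap = field(default_factory=dict)
    n_sets: int = 50
    set_size: int = 20
    baseline_log2_mean: float = 6.0
    feature_log2_sd: float = 1.0
    dispersion: float = 10.0
    subject_sd_log2: float = 0.2
    # serum panel
    n_proteins: int = 1000
    n_protein_sets: int = 20
    protein_set_size: int = 50
    rfu_log2_mean: float = 10.0
    rfu_feature_log2_sd: float = 0.5
    rfu_log_sd: float = 0.5
    n_reference: int = 10
    n_tts: int = 2
    tts_effect_log2: float = 2.0
    overlap_sets: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0 or self.n_subjects_per_arm <= 0:
            raise ValidationError("need at least one feature and one subject per arm")
        if self.n_tts < 0:
            raise ValidationError("n_tts must be >= 0")
        if self.n_sets * self.set_size > self.n_features and not self.overlap_sets:
            raise ValidationError("disjoint sets do not fit in the feature universe")
        if (
            self.n_protein_sets * self.protein_set_size > self.n_proteins
            and not self.overlap_sets
        ):
            raise ValidationError("disjoint protein sets do not fit in the panel")
        dose_order = ("ad26_5e10", "ad26_1e11")  # low, high
        for name, by_arm in self.activated_sets.items():
            for arm, by_tp in by_arm.items():
                if by_tp.get("D8", 0.0) != 0.0:
                    raise ValidationError(
                        f"set {name}, arm {arm}: D8 effect must be 0 (resolved by day 7)"
                    )
            low = by_arm.get(dose_order[0], {})
            high = by_arm.get(dose_order[1], {})
            for tp in set(low) | set(high):
                if low.get(tp, 0.0) > high.get(tp, 0.0):
                    raise ValidationError(
                        f"set {name}, {tp}: low-dose effect exceeds high-dose effect"
                    )


def study_design(
    seed: int = 0,
    effect_log2: float = 1.0,
    n_activated: int = 3,
    boost_fraction: float | None = None,
    **overrides,
) -> SimulationDesign:
    """The default study conditions: ``n_activated`` transcriptomic sets
    (coagulation/platelet, interferon, innate inflammation themed) gain
    ``effect_log2`` at D2 in the high-dose arm and half that in the
    low-dose arm; everything is back to baseline by D8.

    ``boost_fraction`` adds a D58 timepoint whose effect is that fraction
    of the D2 effect (anti-vector immunity blunting the second dose).
    """
    themes = ("COAGULATION_PLATELET", "INTERFERON_SIGNALING", "INNATE_INFLAMMATION")
    names = [themes[i] if i < len(themes) else f"ACTIVATED_{i:02d}" for i in range(n_activated)]
    effects: EffectMap = {}
    if "timepoints" in overrides:
        timepoints = tuple(overrides.pop("timepoints"))
    elif boost_fraction is not None:
        timepoints = ("D1", "D2", "D8", "D58")
    else:
        timepoints = ("D1", "D2", "D8")
    for name in names:
        by_arm: dict[str, dict[str, float]] = {
            "ad26_1e11": {"D2": effect_log2},
            "ad26_5e10": {"D2": effect_log2 / 2.0},
        }
        if boost_fraction is not None:
            by_arm["ad26_1e11"]["D58"] = effect_log2 * boost_fraction
            by_arm["ad26_5e10"]["D58"] = effect_log2 / 2.0 * boost_fraction
        effects[name] = by_arm
    return SimulationDesign(
        activated_sets=effects, timepoints=timepoints, seed=seed, **overrides
    )


def null_design(seed: int = 0, **overrides) -> SimulationDesign:
    """All effects zero: the type-I-error / calibration condition."""
    return SimulationDesign(activated_sets={}, seed=seed, **overrides)


@dataclass
class SimulatedCounts:
    matrix: ExpressionMatrix
    samples: SampleTable
    collection: GeneSetCollection
    activated: dict[str, frozenset[str]]  # ground truth


@dataclass
class SimulatedRfu:
    matrix: ExpressionMatrix
    samples: SampleTable
    collection: GeneSetCollection
    activated: dict[str, frozenset[str]]


def _build_sets(
    rng: np.random.Generator,
    prefix: str,
    feature_ids: list[str],
    activated_names: list[str],
    n_sets: int,
    set_size: int,
    overlap: bool,
) -> GeneSetCollection:
    n_sets = max(n_sets, len(activated_names))
    names = list(activated_names) + [
        f"{prefix}_NULL_{i:03d}" for i in range(n_sets - len(activated_names))
    ]
    if overlap:
        sets = {
            name: frozenset(rng.choice(feature_ids, size=set_size, replace=False))
            for name in names
        }
    else:
        chosen = rng.choice(len(feature_ids), size=n_sets * set_size, replace=False)
        sets = {
            name: frozenset(feature_ids[j] for j in chosen[i * set_size : (i + 1) * set_size])
            for i, name in enumerate(names)
        }
    return GeneSetCollection(sets=sets, provenance={n: "simulated" for n in names})


def simulate_counts(design: SimulationDesign) -> SimulatedCounts:
    """Negative-binomial count matrix for the longitudinal dose-arm design.

    Per cell: ``log2 mu = feature baseline + subject offset + effect`` and
    counts ~ NB(mean ``2**log2mu``, size ``design.dispersion``). The
    returned ground truth maps each activated set name to its members.
    """
    rng = np.random.default_rng(design.seed)
    feature_ids = [f"G{i:04d}" for i in range(design.n_features)]
    collection = _build_sets(
        rng, "RNA", feature_ids, list(design.activated_sets), design.n_sets,
        design.set_size, design.overlap_sets,
    )
    fidx = {f: i for i, f in enumerate(feature_ids)}
    base = design.baseline_log2_mean + rng.normal(
        0.0, design.feature_log2_sd, size=design.n_features
    )

    records = []
    columns = []
    pairable = "D2" in design.timepoints and "D58" in design.timepoints
    for arm in design.arms:
        offsets = rng.normal(0.0, design.subject_sd_log2, size=design.n_subjects_per_arm)
        for s in range(design.n_subjects_per_arm):
            subject = f"{arm}_s{s:02d}"
            for tp in design.timepoints:
                log2mu = base + offsets[s]
                for name, by_arm in design.activated_sets.items():
                    eff = by_arm.get(arm, {}).get(tp, 0.0)
                    if eff:
                        rows = [fidx[f] for f in collection[name]]
                        log2mu = log2mu.copy()
                        log2mu[rows] += eff
                mu = np.exp2(log2mu)
                p = design.dispersion / (design.dispersion + mu)
                counts = rng.negative_binomial(design.dispersion, p)
                sample_id = f"{subject}_{tp}"
                columns.append(counts)
                records.append(
                    {
                        "sample_id": sample_id,
                        "subject_id": subject,
                        "timepoint": tp,
                        "group": arm,
                        "pair_key": f"{subject}_D2D58"
                        if pairable and tp in ("D2", "D58")
                        else None,
                    }
                )
    values = np.column_stack(columns).astype(float)
    matrix = ExpressionMatrix(
        feature_ids=feature_ids,
        sample_ids=[r["sample_id"] for r in records],
        values=values,
        assay_kind="rnaseq_counts",
    )
    samples = SampleTable(frame=pd.DataFrame.from_records(records))
    activated = {name: collection[name] for name in design.activated_sets}
    return SimulatedCounts(matrix, samples, collection, activated)


def simulate_rfu(design: SimulationDesign) -> SimulatedRfu:
    """Log-normal serum RFU panel: healthy reference samples at baseline
    and ``n_tts`` patient samples with ``tts_effect_log2`` added to the
    coagulation/platelet set at day-15-to-19 timepoints."""
    rng = np.random.default_rng(design.seed + 1)
    protein_ids = [f"P{i:04d}" for i in range(design.n_proteins)]
    activated_names = ["COAGULATION_PLATELET"] if design.n_tts >= 0 else []
    collection = _build_sets(
        rng, "PROT", protein_ids, activated_names, design.n_protein_sets,
        design.protein_set_size, design.overlap_sets,
    )
    fidx = {f: i for i, f in enumerate(protein_ids)}
    base = design.rfu_log2_mean + rng.normal(
        0.0, design.rfu_feature_log2_sd, size=design.n_proteins
    )
    tts_rows = [fidx[f] for f in collection["COAGULATION_PLATELET"]]

    columns, records = [], []
    for i in range(design.n_reference):
        log2x = base + rng.normal(0.0, design.rfu_log_sd, size=design.n_proteins)
        columns.append(np.exp2(log2x))
        records.append(
            {
                "sample_id": f"ref_{i:02d}",
                "subject_id": f"ref_{i:02d}",
                "timepoint": "other",
                "group": "healthy_reference",
                "pair_key": None,
            }
        )
    tts_days = ("D15", "D16", "D19")
    for i in range(design.n_tts):
        log2x = base + rng.normal(0.0, design.rfu_log_sd, size=design.n_proteins)
        log2x[tts_rows] += design.tts_effect_log2
        tp = tts_days[i % len(tts_days)]
        columns.append(np.exp2(log2x))
        records.append(
            {
                "sample_id": f"tts_{i:02d}_{tp}",
                "subject_id": f"tts_{i:02d}",
                "timepoint": tp,
                "group": "tts_patient",
                "pair_key": None,
            }
        )
    values = np.column_stack(columns)
    matrix = ExpressionMatrix(
        feature_ids=protein_ids,
        sample_ids=[r["sample_id"] for r in records],
        values=values,
        assay_kind="soma_rfu",
    )
    samples = SampleTable(frame=pd.DataFrame.from_records(records))
    activated = {n: collection[n] for n in activated_names}
    return SimulatedRfu(matrix, samples, collection, activated)


@dataclass
class SimulatedPlate:
    calibrator_replicates: pd.DataFrame
    calibrator_reference: pd.Series
    qc_replicates: pd.DataFrame
    qc_reference: pd.Series
    shift: float


def simulate_plate(
    design: SimulationDesign,
    n_calibrators: int = 5,
    n_qc: int = 3,
    shift: float = 1.0,
    replicate_noise_log2: float = 0.05,
) -> SimulatedPlate:
    """Calibrator and QC replicate tables for one plate.

    Per-feature replicate medians equal ``reference * shift`` exactly
    (replicate noise is renormalised to median one per feature), so the
    plate scale factor computed downstream is exactly ``1 / shift``.
    """
    if n_calibrators < 1 or n_qc < 1:
        raise ValidationError("need at least one calibrator and one QC replicate")
    if shift <= 0:
        raise ValidationError("shift must be positive")
    rng = np.random.default_rng(design.seed + 2)
    protein_ids = [f"P{i:04d}" for i in range(design.n_proteins)]
    ref = np.exp2(
        design.rfu_log2_mean
        + rng.normal(0.0, design.rfu_feature_log2_sd, size=design.n_proteins)
    )
    qc_ref = np.exp2(
        design.rfu_log2_mean
        + rng.normal(0.0, design.rfu_feature_log2_sd, size=design.n_proteins)
    )

    def replicate_table(reference: np.ndarray, n_rep: int) -> pd.DataFrame:
        noise = np.exp2(
            rng.normal(0.0, replicate_noise_log2, size=(design.n_proteins, n_rep))
        )
        noise /= np.median(noise, axis=1, keepdims=True)  # exact median 1 per feature
        return pd.DataFrame(
            reference[:, None] * shift * noise,
            index=pd.Index(protein_ids, name="feature_id"),
            columns=[f"rep_{j}" for j in range(n_rep)],
        )

    return SimulatedPlate(
        calibrator_replicates=replicate_table(ref, n_calibrators),
        calibrator_reference=pd.Series(ref, index=protein_ids, name="reference"),
        qc_replicates=replicate_table(qc_ref, n_qc),
        qc_reference=pd.Series(qc_ref, index=protein_ids, name="qc_reference"),
        shift=shift,
    )


def with_seed(design: SimulationDesign, seed: int) -> SimulationDesign:
    """Same design, different seed (for replicate-based power estimates)."""
    return replace(design, seed=seed)
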