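"""Synthetic inputs for the whole pipeline.

Experimental mutant response values of the kind this package analyses
(delta-EC50 and second-messenger readouts for olfactory-receptor point
mutants) live in curated databases and are rarely redistributable, and
published property tables may not be shippable either.  This module generates
every input the pipeline needs -- property tables, receptor sequences, CA
point-cloud structures, mutant datasets with a *known* linear dependence on a
few properties, and labelled increase/decrease sets -- so every stage can be
exercised end-to-end, with ground truth recorded next to the data for
closed-loop recovery tests.

The statistical structure mirrors what the analysis assumes: the response is
a linear function of a small property subset's feature values plus additive
Gaussian noise, with the noise SD parameterized as a fraction of the
noiseless response SD (so difficulty is scale-free).  Default sizes mirror
the small strata of real mutant studies (6-28 mutants, default 28, split
15 increase / 13 decrease for classification).

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DatasetValidationError
from .features import (
    MutantDataset,
    MutantRecord,
    StructureContext,
    build_feature_matrix,
)
from .properties import RESIDUES, PropertyTable

_PROPERTY_FAMILIES = (
    "hydrophobicity", "polarity", "volume", "bulkiness", "flexibility",
    "helix_propensity", "sheet_propensity", "coil_propensity", "isoelectric",
    "refractivity", "unfold_asa", "unfold_gibbs", "unfold_enthalpy",
    "unfold_entropy", "access_reduction", "compressibility", "charge_density",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one synthetic mutant dataset.

    ``noise_sd`` is the response noise SD as a fraction of the noiseless
    response SD.  ``true_subset`` lists the property ids carrying signal
    (chosen at random from the table when None).  ``class_margin`` (labelled
    sets) is the minimum signed-response magnitude, in units of the noiseless
    score SD; larger margins give wider class separation in feature space.
    """

    seed: int = 0
    n_mutants: int = 28
    n_properties: int = 49
    true_subset: tuple[str, ...] | None = None
    n_true: int = 3
    beta0: float = 0.5
    betas: tuple[float, ...] | None = None
    noise_sd: float = 0.05
    encoding: str = "delta"
    k: int = 1
    radius: float = 8.0
    sequence_length: int = 60
    class_margin: float = 1.0
    geometry: str = "helix"

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_mutants < 3:
            raise ValueError("n_mutants must be >= 3")
        if self.class_margin < 0:
            raise ValueError("class_margin must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually used; enables closed-loop recovery tests."""

    true_subset: tuple[str, ...]
    beta0: float
    betas: tuple[float, ...]
    encoding: str
    k: int
    radius: float
    noise: np.ndarray
    noiseless_response: np.ndarray
    feature_columns: tuple[str, ...] = ()


def simulate_property_table(n_properties: int, seed: int) -> PropertyTable:
    """A deterministic pseudo property table: ``n_properties`` x 20 residues.

    Each property draws its 20 residue values uniformly from a random
    interval (random location and width), so raw scales differ in units and
    range the way real physicochemical scales do; normalization is exercised
    non-trivially.  Continuous draws make degenerate (constant) properties
    a zero-probability event.
    """
    if n_properties < 1:
        raise ValueError("n_properties must be >= 1")
    rng = np.random.default_rng(seed)
    rows = {}
    descriptions = {}
    for i in range(n_properties):
        family = _PROPERTY_FAMILIES[i % len(_PROPERTY_FAMILIES)]
        pid = f"{family}_s{i + 1:02d}"
        lo = rng.uniform(-10.0, 10.0)
        width = rng.uniform(1.0, 20.0)
        rows[pid] = rng.uniform(lo, lo + width, size=20)
        descriptions[pid] = f"synthetic stand-in scale (family: {family})"
    raw = pd.DataFrame(rows, index=list(RESIDUES)).T
    return PropertyTable.from_raw(raw, descriptions)


def simulate_structure(n_residues: int, geometry: str = "helix", seed: int = 0,
                       sequence: str | None = None) -> StructureContext:
    """A CA point cloud: ideal alpha-helix or randomly packed points.

    Helix: rise 1.5 A per residue, 100 degrees twist, 2.3 A radius, so an
    8 A neighbourhood holds several residues.  Random packing places points
    sequentially with minimum separation 3.8 A (the CA-CA virtual bond).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(RESIDUES), size=n_residues))
    if len(sequence) != n_residues:
        raise ValueError("sequence length must equal n_residues")
    if geometry == "helix":
        i = np.arange(n_residues)
        theta = np.deg2rad(100.0) * i
        coords = np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
        )
    elif geometry == "random-packed":
        pts = [rng.uniform(0, 10, size=3)]
        while len(pts) < n_residues:
            cand = rng.uniform(0, max(10.0, n_residues ** (1 / 3) * 6), size=3)
            if min(np.linalg.norm(cand - p) for p in pts) >= 3.8:
                pts.append(cand)
        coords = np.array(pts)
    else:
        raise ValueError(f"geometry must be 'helix' or 'random-packed', got {geometry!r}")
    return StructureContext(
        positions=tuple(range(1, n_residues + 1)),
        residues=tuple(sequence),
        coords=coords,
    )


def _draw_mutants(rng: np.random.Generator, sequence: str, n: int,
                  receptor_id: str) -> list[MutantRecord]:
    records = []
    codes = list(RESIDUES)
    for _ in range(n):
        pos = int(rng.integers(1, len(sequence) + 1))
        wild = sequence[pos - 1]
        mutant = wild
        while mutant == wild:
            mutant = codes[int(rng.integers(0, 20))]
        # TM-like stratum: central half of the sequence
        loc = "TM" if len(sequence) / 4 <= pos <= 3 * len(sequence) / 4 else "loop"
        records.append(
            MutantRecord(receptor_id=receptor_id, position=pos, wild=wild,
                         mutant=mutant, response=0.0, location_class=loc)
        )
    return records


def _with_responses(records, responses):
    return [replace(r, response=float(y)) for r, y in zip(records, responses)]


def simulate_mutation_dataset(
    table: PropertyTable, config: SimulationConfig, max_retries: int = 20
) -> tuple[MutantDataset, GroundTruth]:
    """A mutant dataset whose response is linear in a known property subset.

    Draws wild/mutant pairs and positions on a generated sequence, computes
    the configured encoding's features for the true subset through the real
    feature code, and sets

        response = beta0 + sum(beta_s * feature_s) + eps,
        eps ~ N(0, (noise_sd * SD(noiseless response))^2).

    A draw in which some true-subset feature is constant across mutants is
    regenerated (bounded retries) since its coefficient would be
    unidentifiable.
    """
    rng = np.random.default_rng(config.seed)
    if config.true_subset is None:
        subset = tuple(
            sorted(str(p) for p in
                   rng.choice(table.property_ids, size=config.n_true, replace=False))
        )
    else:
        subset = tuple(str(p) for p in config.true_subset)
    if config.betas is None:
        betas = tuple(
            float(rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])) for _ in subset
        )
    else:
        betas = tuple(config.betas)
    if len(betas) != len(subset):
        raise ValueError("betas and true_subset differ in length")
    # feature columns come back in table order; keep betas aligned with them
    order = {p: i for i, p in enumerate(table.property_ids)}
    ranks = sorted(range(len(subset)), key=lambda j: order[subset[j]])
    subset = tuple(subset[j] for j in ranks)
    betas = tuple(betas[j] for j in ranks)

    for attempt in range(max_retries + 1):
        seq = "".join(rng.choice(list(RESIDUES), size=config.sequence_length))
        records = _draw_mutants(rng, seq, config.n_mutants, receptor_id="synthOR")
        structure = None
        if config.encoding == "structural":
            structure = simulate_structure(
                config.sequence_length, config.geometry,
                seed=int(rng.integers(0, 2**31 - 1)), sequence=seq,
            )
        base = MutantDataset(
            records=records, sequence=seq, structure=structure,
            response_label="synthetic response",
        )
        fm = build_feature_matrix(
            table, base, encodings=[config.encoding], property_ids=list(subset),
            k=config.k, radius=config.radius,
        )
        X = fm.frame.to_numpy(dtype=float)
        if np.any(np.ptp(X, axis=0) == 0):
            if attempt == max_retries:
                raise DatasetValidationError(
                    "could not draw a dataset with non-constant true-subset features"
                )
            continue
        noiseless = config.beta0 + X @ np.asarray(betas)
        signal_sd = float(noiseless.std())
        if signal_sd == 0:
            if not np.any(np.asarray(betas)):
                signal_sd = 1.0  # null model (all betas 0): noise in absolute units
            elif attempt == max_retries:
                raise DatasetValidationError("noiseless response is constant")
            else:
                continue
        noise = rng.normal(0.0, config.noise_sd * signal_sd, size=config.n_mutants)
        dataset = MutantDataset(
            records=_with_responses(records, noiseless + noise),
            sequence=seq, structure=structure,
            response_label="synthetic response",
        )
        truth = GroundTruth(
            true_subset=subset, beta0=config.beta0, betas=betas,
            encoding=config.encoding, k=config.k, radius=config.radius,
            noise=noise, noiseless_response=noiseless,
            feature_columns=tuple(fm.column_ids),
        )
        return dataset, truth
    raise AssertionError("unreachable")


def simulate_classification_dataset(
    table: PropertyTable,
    config: SimulationConfig,
    n_increase: int = 15,
    n_decrease: int = 13,
) -> tuple[MutantDataset, GroundTruth]:
    """A labelled increase/decrease set with controllable separability.

    Candidate mutants are drawn in a pool, scored by the true-subset linear
    combination (plus noise), and the top ``n_increase`` / bottom
    ``n_decrease`` scorers are kept.  Responses are centred on the class
    boundary and pushed apart by ``class_margin`` (in units of the score SD),
    so every response magnitude exceeds the margin and -- because the score
    is a function of the features -- the classes separate in feature space
    as the margin grows.  With all-zero betas the score is pure noise:
    labels are then independent of the features (a null dataset).

    Returns the mutant dataset (signed responses; label = sign) and the
    ground truth.  Labels follow from :func:`mutprop.discrimination.label_by_sign`.
    """
    n_total = n_increase + n_decrease
    cfg = replace(config, n_mutants=max(4 * n_total, n_total + 8))
    rng = np.random.default_rng(config.seed)
    if cfg.true_subset is None:
        subset = tuple(
            sorted(str(p) for p in
                   rng.choice(table.property_ids, size=cfg.n_true, replace=False))
        )
        cfg = replace(cfg, true_subset=subset)
    if cfg.betas is None:
        betas = tuple(
            float(rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])) for _ in cfg.true_subset
        )
        cfg = replace(cfg, betas=betas)
    # align (subset, betas) with the table-order feature columns
    order = {p: i for i, p in enumerate(table.property_ids)}
    ranks = sorted(range(len(cfg.true_subset)), key=lambda j: order[str(cfg.true_subset[j])])
    cfg = replace(
        cfg,
        true_subset=tuple(str(cfg.true_subset[j]) for j in ranks),
        betas=tuple(cfg.betas[j] for j in ranks),
    )
    pool_seed = int(rng.integers(0, 2**31 - 1))
    beta_arr = np.asarray(cfg.betas)
    pool_n = max(4 * n_total, n_total + 8)
    # grow the candidate pool until the kept classes are class_margin score-SDs
    # apart (discarding middle scorers widens the gap in feature space)
    for doubling in range(7):
        pool, _ = simulate_mutation_dataset(
            table, replace(cfg, seed=pool_seed, noise_sd=0.0, n_mutants=pool_n)
        )
        fm = build_feature_matrix(
            table, pool, encodings=[cfg.encoding], property_ids=list(cfg.true_subset),
            k=cfg.k, radius=cfg.radius,
        )
        X = fm.frame.to_numpy(dtype=float)
        if np.all(beta_arr == 0):
            score = rng.normal(size=len(X))  # pure-noise scores: null labels
        else:
            score = X @ beta_arr
        score_sd = float(score.std()) or 1.0
        order = np.argsort(-score, kind="stable")
        inc_idx = order[:n_increase]
        dec_idx = order[-n_decrease:]
        gap = float(score[inc_idx].min() - score[dec_idx].max())
        if np.all(beta_arr == 0) or gap >= config.class_margin * score_sd:
            break
        pool_n *= 2
    else:
        warnings.warn(
            f"requested class margin {config.class_margin} score-SDs not reached "
            f"(achieved {gap / score_sd:.2f}); using the widest pool drawn",
            stacklevel=2,
        )
    boundary = 0.5 * (score[inc_idx].min() + score[dec_idx].max())
    centred = score - boundary
    responses = np.where(
        centred >= 0,
        centred + config.class_margin * score_sd,
        centred - config.class_margin * score_sd,
    )
    keep = np.concatenate([inc_idx, dec_idx])
    records = _with_responses(
        [pool.records[i] for i in keep], responses[keep]
    )
    dataset = MutantDataset(
        records=records, sequence=pool.sequence, structure=pool.structure,
        response_label="synthetic signed response",
    )
    truth = GroundTruth(
        true_subset=cfg.true_subset, beta0=0.0, betas=cfg.betas,
        encoding=cfg.encoding, k=cfg.k, radius=cfg.radius,
        noise=np.zeros(n_total), noiseless_response=responses[keep],
        feature_columns=tuple(fm.column_ids),
    )
    return dataset, truth
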