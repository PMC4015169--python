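"""Synthetic benchmark datasets with the structure the protocols assume.

Three scenarios emulate the shapes of the published benchmark sets without
any external data:

* ``dipeptide_additive`` — a peptide-only regression set: random dipeptides
  whose activity is linear in a chosen descriptor encoding plus Gaussian
  noise (an ACE-inhibitor-like QSAM set; ground-truth weights are kept for
  recovery tests);
* ``mutant_panel`` — point mutants of one base sequence crossed with
  surrogate-fingerprint compounds; activity = compound main effect + a
  target effect carried by the descriptor encoding of the mutated positions
  + a low-rank compound x target interaction + noise, subsampled to a
  requested matrix completeness (an NNRTI/PI-like regression panel);
* ``gpcr_classification`` — a receptor panel grouped into sequence families
  (one deliberately dispersed), each receptor with chemically clustered
  actives and diverse (presumed) inactives (a GPCR-like classification set).

Compound surrogates are random bit vectors (``"bits:0101..."``) so the
generators carry no chemistry dependency; pass ``emit_smiles=True`` to the
mutant panel for an end-to-end run through the RDKit featurizer instead.
All generators are deterministic in their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import ActivityRecord, PCMDataset, TargetEntry
from .encoding import DescriptorSetSpec, encode_sequence
from .tables import NATURAL_AAS, load_descriptor_table

__all__ = [
    "SimulationConfig",
    "make_dipeptide_set",
    "make_mutant_panel",
    "make_gpcr_classification_set",
    "simulate",
]

# a small pool of drug-like SMILES used when real structures are requested
_SMILES_POOL = [
    "CCO", "CC(=O)O", "c1ccccc1", "c1ccncc1", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "CC(=O)Nc1ccc(O)cc1", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "NCCc1ccc(O)c(O)c1",
    "CC(N)Cc1ccccc1", "OCC1OC(O)C(O)C(O)C1O",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs shared by the three generator scenarios."""

    scenario: str = "dipeptide_additive"
    n_compounds: int = 451
    n_targets: int = 14
    sequence_length: int = 99
    n_mutated_positions: int = 24
    completeness: float = 0.64
    noise_sd: float = 0.3
    effect_table: str = "zscales3"
    class_threshold: float = 7.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.completeness <= 1):
            raise ValueError("completeness must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _standardized(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    return (values - values.mean()) / sd if sd > 0 else values - values.mean()


def make_dipeptide_set(n_peptides: int = 58, noise_sd: float = 0.3,
                       effect_table: str = "zscales3", signal_sd: float = 1.2,
                       seed: int = 0, name: str = "dipeptides") -> PCMDataset:
    """Peptide-only regression set with additive descriptor-space signal.

    Activity is ``6 + s * (w . encode(effect_table, dipeptide)) +
    N(0, noise_sd)`` with weights drawn once per dataset and the linear
    signal standardized to ``signal_sd`` log units (a realistic pIC50
    spread); the truth is stored under ``metadata["ground_truth"]``.
    """
    rng = np.random.default_rng(seed)
    table = load_descriptor_table(effect_table)
    spec = DescriptorSetSpec(base_tables=(table,))
    weights = rng.normal(size=2 * table.n_components)
    aas = list(NATURAL_AAS)
    peptides = ["".join(rng.choice(aas, size=2)) for _ in range(n_peptides)]
    encodings = np.vstack([encode_sequence(spec, pep).feature_vector
                           for pep in peptides])
    raw = encodings @ weights
    signal = signal_sd * _standardized(raw)  # still linear in the encoding
    targets, activities = [], []
    for i, pep in enumerate(peptides):
        tid = f"pep{i + 1:04d}"
        value = 6.0 + float(signal[i]) + rng.normal(scale=noise_sd)
        targets.append(TargetEntry(target_id=tid, residue_string=pep,
                                   source_note="synthetic dipeptide"))
        activities.append(ActivityRecord(compound_id=tid, target_id=tid,
                                         value=value))
    return PCMDataset(
        name=name, task="regression", targets=targets, activities=activities,
        peptide_only=True,
        metadata={"scenario": "dipeptide_additive", "seed": seed,
                  "noise_sd": noise_sd, "effect_table": effect_table,
                  "signal_sd": signal_sd,
                  "ground_truth": {"weights": weights.tolist(),
                                   "intercept": 6.0}})


def _random_bits(rng, n_bits: int) -> np.ndarray:
    return rng.integers(0, 2, size=n_bits)


def _bits_structure(bits: np.ndarray) -> str:
    return "bits:" + "".join(str(int(b)) for b in bits)


def make_mutant_panel(n_targets: int = 14, n_compounds: int = 451,
                      sequence_length: int = 99, n_mutated_positions: int = 24,
                      max_mutations: int = 13, completeness: float = 0.64,
                      noise_sd: float = 0.3, effect_table: str = "zscales3",
                      n_fingerprint_bits: int = 128, interaction_rank: int = 2,
                      interaction_scale: float = 0.5, target_effect_scale: float = 1.0,
                      singleton: bool = False, singleton_effect: float = 3.0,
                      emit_smiles: bool = False, seed: int = 0,
                      name: str = "mutant_panel") -> PCMDataset:
    """Point-mutant regression panel with a sparse activity matrix.

    Mutations are confined to a pool of ``n_mutated_positions`` columns of a
    random base sequence; each mutant carries 1..``max_mutations`` of them.
    With ``singleton=True`` the first mutant carries one private mutation at
    a pool column no other mutant touches, plus a strong private activity
    offset — the hard extrapolation case for leave-one-sequence-out
    validation.  The record list is subsampled to the requested completeness
    with at least one record per target.
    """
    if max_mutations > n_mutated_positions:
        raise ValueError("max_mutations cannot exceed the mutated-position pool")
    rng = np.random.default_rng(seed)
    aas = list(NATURAL_AAS)
    base = "".join(rng.choice(aas, size=sequence_length))
    pool = sorted(rng.choice(sequence_length, size=n_mutated_positions,
                             replace=False).tolist())  # 0-based
    shared_pool = pool[1:] if singleton else pool
    targets, pool_strings = [], []
    for t in range(n_targets):
        seq = list(base)
        if singleton and t == 0:
            positions = [pool[0]]
        else:
            n_mut = int(rng.integers(1, min(max_mutations, len(shared_pool)) + 1))
            positions = rng.choice(shared_pool, size=n_mut, replace=False)
        for p in positions:
            current = seq[p]
            seq[p] = rng.choice([a for a in aas if a != current])
        targets.append(TargetEntry(target_id=f"mut{t + 1:03d}",
                                   residue_string="".join(seq),
                                   source_note=f"{len(positions)} point mutation(s)"))
        pool_strings.append("".join(seq[p] for p in pool))
    table = load_descriptor_table(effect_table)
    spec = DescriptorSetSpec(base_tables=(table,))
    v = rng.normal(size=len(pool) * table.n_components)
    target_eff = _standardized(np.array(
        [float(v @ encode_sequence(spec, s).feature_vector) for s in pool_strings]))
    target_eff = target_effect_scale * target_eff
    if singleton:
        target_eff[0] += singleton_effect

    bit_matrix = np.vstack([_random_bits(rng, n_fingerprint_bits)
                            for _ in range(n_compounds)])
    if emit_smiles:
        structures = [str(_SMILES_POOL[i % len(_SMILES_POOL)]) for i in range(n_compounds)]
    else:
        structures = [_bits_structure(row) for row in bit_matrix]
    compounds = [(f"cmp{c + 1:05d}", structures[c]) for c in range(n_compounds)]
    w = rng.normal(size=n_fingerprint_bits)
    compound_eff = _standardized((bit_matrix - 0.5) @ w)
    U = rng.normal(size=(n_compounds, interaction_rank))
    V = rng.normal(size=(n_targets, interaction_rank))
    interaction = U @ V.T
    interaction = interaction_scale * (interaction - interaction.mean()) / interaction.std()

    cells = [(c, t) for c in range(n_compounds) for t in range(n_targets)]
    n_records = int(round(completeness * len(cells)))
    n_records = max(n_records, n_targets)
    chosen = []
    used = set()
    for t in range(n_targets):  # guarantee one record per target
        c = int(rng.integers(n_compounds))
        chosen.append((c, t))
        used.add((c, t))
    remaining = [cell for cell in cells if cell not in used]
    extra = rng.choice(len(remaining), size=n_records - n_targets, replace=False)
    chosen.extend(remaining[i] for i in extra)
    activities = []
    for c, t in sorted(chosen):
        value = (6.0 + compound_eff[c] + target_eff[t] + interaction[c, t]
                 + rng.normal(scale=noise_sd))
        activities.append(ActivityRecord(compound_id=compounds[c][0],
                                         target_id=targets[t].target_id,
                                         value=float(value)))
    return PCMDataset(
        name=name, task="regression", compounds=compounds, targets=targets,
        activities=activities,
        metadata={"scenario": "mutant_panel", "seed": seed,
                  "noise_sd": noise_sd, "effect_table": effect_table,
                  "mutated_pool_1based": [p + 1 for p in pool],
                  "singleton_target": targets[0].target_id if singleton else "",
                  "requested_completeness": completeness})


def make_gpcr_classification_set(n_targets: int = 32, n_families: int = 8,
                                 n_actives: int = 100, n_inactives: int = 75,
                                 n_presumed_inactives: int = 25,
                                 sequence_length: int = 30,
                                 n_fingerprint_bits: int = 128,
                                 within_family_divergence: float = 0.1,
                                 active_flip_prob: float = 0.1,
                                 class_threshold: float = 7.0,
                                 dispersed_family: bool = True, seed: int = 0,
                                 name: str = "gpcr_panel") -> PCMDataset:
    """Receptor-family classification panel with one dispersed family.

    Targets are grouped into ``n_families`` sequence families; members of a
    tight family share a consensus binding site and a chemical prototype for
    their actives, so held-out members remain predictable from their
    siblings.  The last family is dispersed (independent sequences and
    prototypes) when ``dispersed_family`` is set, reproducing the
    poorly-extrapolating-singleton pattern.  Per target: ``n_actives``
    actives near the prototype (latent pKi above the threshold) and
    ``n_inactives`` + ``n_presumed_inactives`` diverse inactives below it.
    """
    rng = np.random.default_rng(seed)
    aas = list(NATURAL_AAS)
    groups = np.array_split(np.arange(n_targets), n_families)
    targets, family_of, prototypes = [], {}, {}
    for f, members in enumerate(groups):
        consensus = rng.choice(aas, size=sequence_length)
        family_proto = _random_bits(rng, n_fingerprint_bits)
        dispersed = dispersed_family and f == n_families - 1
        for t in members:
            tid = f"rec{t + 1:03d}"
            if dispersed:
                seq = rng.choice(aas, size=sequence_length)
                proto = _random_bits(rng, n_fingerprint_bits)
            else:
                seq = consensus.copy()
                flip = rng.random(sequence_length) < within_family_divergence
                seq[flip] = rng.choice(aas, size=int(flip.sum()))
                proto = family_proto.copy()
                pflip = rng.random(n_fingerprint_bits) < 0.05
                proto[pflip] = 1 - proto[pflip]
            targets.append(TargetEntry(target_id=tid,
                                       residue_string="".join(seq),
                                       source_note=f"family {f}"
                                                   + (" (dispersed)" if dispersed else "")))
            family_of[tid] = f
            prototypes[tid] = proto
    compounds, activities = [], []
    counter = 0
    for entry in targets:
        proto = prototypes[entry.target_id]
        for _ in range(n_actives):
            bits = proto.copy()
            flip = rng.random(n_fingerprint_bits) < active_flip_prob
            bits[flip] = 1 - bits[flip]
            latent = class_threshold + abs(rng.normal(1.0, 0.5))
            counter += 1
            cid = f"cmp{counter:06d}"
            compounds.append((cid, _bits_structure(bits)))
            activities.append(ActivityRecord(
                compound_id=cid, target_id=entry.target_id,
                class_label="active" if latent > class_threshold else "inactive"))
        for kind in range(n_inactives + n_presumed_inactives):
            bits = _random_bits(rng, n_fingerprint_bits)
            offset = 1.0 if kind < n_inactives else 2.0
            latent = class_threshold - abs(rng.normal(offset, 0.5))
            counter += 1
            cid = f"cmp{counter:06d}"
            compounds.append((cid, _bits_structure(bits)))
            activities.append(ActivityRecord(
                compound_id=cid, target_id=entry.target_id,
                class_label="active" if latent > class_threshold else "inactive"))
    dispersed_ids = [t.target_id for t in targets
                     if family_of[t.target_id] == n_families - 1] if dispersed_family else []
    return PCMDataset(
        name=name, task="classification", compounds=compounds, targets=targets,
        activities=activities,
        metadata={"scenario": "gpcr_classification", "seed": seed,
                  "families": {t.target_id: family_of[t.target_id] for t in targets},
                  "dispersed_targets": dispersed_ids,
                  "class_threshold": class_threshold})


def simulate(config: SimulationConfig) -> PCMDataset:
    """Dispatch a :class:`SimulationConfig` to its scenario generator."""
    if config.scenario == "dipeptide_additive":
        return make_dipeptide_set(n_peptides=config.n_targets,
                                  noise_sd=config.noise_sd,
                                  effect_table=config.effect_table,
                                  seed=config.seed)
    if config.scenario == "mutant_panel":
        return make_mutant_panel(n_targets=config.n_targets,
                                 n_compounds=config.n_compounds,
                                 sequence_length=config.sequence_length,
                                 n_mutated_positions=config.n_mutated_positions,
                                 completeness=config.completeness,
                                 noise_sd=config.noise_sd,
                                 effect_table=config.effect_table,
                                 seed=config.seed)
    if config.scenario == "gpcr_classification":
        return make_gpcr_classification_set(n_targets=config.n_targets,
                                            sequence_length=config.sequence_length,
                                            class_threshold=config.class_threshold,
                                            seed=config.seed)
    raise ValueError(f"unknown scenario {config.scenario!r}")
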