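"""Synthetic phenotypic screens with a known structure–activity ground truth.

The original training data — a 640-compound fibrosis screen read out as
RFP (αSMA) and EGFP (collagen) fold-over-control intensities — is not
publicly deposited, and the candidate library it was applied to (ChEMBL)
is far beyond desk scale.  This module therefore generates compound
libraries and screens with the same *statistical* structure so every
pipeline stage runs and is testable offline:

* molecules are assembled from a small fragment grammar and fingerprinted;
* a sparse ground truth attaches activity to a few fingerprint bits: a
  compound carrying an effect bit has its expected RFP/EGFP lowered by
  that bit's effect size, with the two targets' effects positively
  correlated (shared latent draw), mirroring the coupled αSMA/collagen
  phenotype;
* intensities are centred at the untreated control (1.0), carry additive
  Gaussian noise, and are clipped at zero.

Effects act on fingerprint bits rather than on latent chemistry, so the
tree model class can represent the ground truth exactly — which makes
noise-free recovery and enrichment tests sharp rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import (
    Fingerprint,
    Molecule,
    ReferenceSet,
    ecfp,
    parse_smiles,
)
from .pct import ScreenRecord, TrainingSet, fingerprints_to_matrix

# Fragments chosen so that plain concatenation of any sequence (optionally
# interleaved with linkers) remains a valid SMILES: every fragment's first
# and last written atom can accept one more single bond.
DEFAULT_FRAGMENTS: tuple[str, ...] = (
    "c1ccccc1",
    "C1CCCCC1",
    "c1ccncc1",
    "C1CCNCC1",
    "C1CCOC1",
    "CCO",
    "CCN",
    "CC(=O)O",
    "CC(=O)N",
    "COC",
    "CNC",
    "CC(C)C",
    "C(Cl)C",
    "C(F)(F)C",
    "CS",
    "C=CC",
)

DEFAULT_LINKERS: tuple[str, ...] = ("", "C", "CC", "O", "N")


@dataclass(frozen=True)
class FragmentGrammar:
    """Assembly rules for synthetic molecules.

    Molecules are built by concatenating 1..max_fragments fragments,
    joined by randomly chosen linkers.  Every assembled string must parse
    under the chem layer; :func:`sample_library` asserts this.
    """

    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS
    linkers: tuple[str, ...] = DEFAULT_LINKERS
    max_fragments: int = 4

    def __post_init__(self) -> None:
        if len(self.fragments) == 0:
            raise ValueError("grammar needs at least one fragment")
        if self.max_fragments < 1:
            raise ValueError("max_fragments must be >= 1")


def sample_library(
    n: int,
    grammar: FragmentGrammar = FragmentGrammar(),
    seed: int = 0,
    id_prefix: str = "SYN",
) -> list[Molecule]:
    """Sample ``n`` molecules from the grammar; ids are ``SYN-000001``..."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mols = []
    for i in range(n):
        k = int(rng.integers(1, grammar.max_fragments + 1))
        parts = [
            grammar.fragments[int(j)]
            for j in rng.integers(0, len(grammar.fragments), size=k)
        ]
        linkers = [
            grammar.linkers[int(j)]
            for j in rng.integers(0, len(grammar.linkers), size=max(k - 1, 0))
        ]
        smiles = parts[0]
        for linker, part in zip(linkers, parts[1:]):
            smiles += linker + part
        mols.append(parse_smiles(smiles, id=f"{id_prefix}-{i + 1:06d}"))
    return mols


@dataclass(frozen=True)
class GroundTruthModel:
    """Sparse bit-level structure–activity ground truth.

    ``effect_bits`` lists (bit index, rfp effect, egfp effect): a compound
    whose fingerprint carries the bit has its expected intensity lowered
    by the effect size (fold-over-control units).  ``noise_sd`` is the
    per-target additive noise sd; ``per_compound_noise`` optionally
    overrides it compound-by-compound (heteroscedastic scenarios).
    ``baseline`` is the untreated-control level.
    """

    nbits: int
    effect_bits: tuple[tuple[int, float, float], ...]
    noise_sd: tuple[float, float] = (0.08, 0.08)
    baseline: float = 1.0

    def __post_init__(self) -> None:
        bits = [b for b, _, _ in self.effect_bits]
        if any(b < 0 or b >= self.nbits for b in bits):
            raise ValueError("effect bit index out of range")
        if len(bits) != len(set(bits)):
            raise ValueError("effect bits must be distinct")
        if any(s < 0 for s in self.noise_sd):
            raise ValueError("noise_sd must be >= 0")

    def expected_targets(self, fp: Fingerprint) -> tuple[float, float]:
        """Noise-free (rfp, egfp) for a fingerprint, clipped at zero."""
        rfp = egfp = self.baseline
        for bit, rfp_eff, egfp_eff in self.effect_bits:
            if bit in fp.bits:
                rfp -= rfp_eff
                egfp -= egfp_eff
        return max(rfp, 0.0), max(egfp, 0.0)

    def carries_effect(self, fp: Fingerprint) -> bool:
        return any(bit in fp.bits for bit, _, _ in self.effect_bits)


def make_ground_truth(
    nbits: int,
    k_effects: int,
    effect_scale: tuple[float, float] = (0.3, 0.6),
    noise_sd: float | tuple[float, float] = 0.08,
    seed: int = 0,
    candidate_bits: Optional[Sequence[int]] = None,
) -> GroundTruthModel:
    """Draw a ground truth with ``k_effects`` distinct effect bits.

    RFP and EGFP effect sizes share a latent draw from ``effect_scale``
    with small independent jitter, so the two targets' effects are
    positively correlated.  ``candidate_bits`` restricts which bits may
    carry effects (scenario builders pass bits actually populated by the
    library so the signal is realisable).
    """
    if nbits < 2:
        raise ValueError("nbits must be >= 2")
    if k_effects < 0:
        raise ValueError("k_effects must be >= 0")
    pool = np.arange(nbits) if candidate_bits is None else np.asarray(
        sorted(set(candidate_bits)), dtype=int
    )
    if k_effects > pool.size:
        raise ValueError(
            f"k_effects={k_effects} exceeds the {pool.size} candidate bits"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=k_effects, replace=False)
    lo, hi = effect_scale
    effects = []
    for bit in sorted(int(b) for b in chosen):
        latent = rng.uniform(lo, hi)
        jitter = rng.normal(0.0, 0.05 * max(latent, 1e-9), size=2)
        rfp_eff = float(np.clip(latent + jitter[0], 0.0, None))
        egfp_eff = float(np.clip(latent + jitter[1], 0.0, None))
        effects.append((bit, rfp_eff, egfp_eff))
    if isinstance(noise_sd, (int, float)):
        noise = (float(noise_sd), float(noise_sd))
    else:
        noise = (float(noise_sd[0]), float(noise_sd[1]))
    return GroundTruthModel(
        nbits=nbits, effect_bits=tuple(effects), noise_sd=noise
    )


def simulate_screen(
    mols: Sequence[Molecule],
    gt: GroundTruthModel,
    radius: int = 2,
    seed: int = 0,
    fingerprints: Optional[Sequence[Fingerprint]] = None,
    per_compound_noise: Optional[Sequence[float]] = None,
) -> TrainingSet:
    """Simulate screen readouts for a molecule list under a ground truth.

    Per compound: ``rfp = clip(baseline − Σ effects·bit + ε, 0)`` and
    analogously for EGFP, ε ~ N(0, sd) drawn from the seeded generator.
    ``per_compound_noise`` replaces the model's per-target sd with one sd
    per compound (applied to both targets)."""
    if fingerprints is None:
        fingerprints = [ecfp(m, radius=radius, nbits=gt.nbits) for m in mols]
    if len(fingerprints) != len(mols):
        raise ValueError("one fingerprint per molecule required")
    rng = np.random.default_rng(seed)
    records = []
    for i, (mol, fp) in enumerate(zip(mols, fingerprints)):
        rfp0, egfp0 = gt.expected_targets(fp)
        if per_compound_noise is not None:
            sd_rfp = sd_egfp = float(per_compound_noise[i])
        else:
            sd_rfp, sd_egfp = gt.noise_sd
        rfp = rfp0 + rng.normal(0.0, sd_rfp) if sd_rfp > 0 else rfp0
        egfp = egfp0 + rng.normal(0.0, sd_egfp) if sd_egfp > 0 else egfp0
        records.append(
            ScreenRecord(
                id=mol.id,
                fingerprint=fp,
                rfp=max(rfp, 0.0),
                egfp=max(egfp, 0.0),
            )
        )
    return TrainingSet(records)


# ---------------------------------------------------------------------------
# scenario builders


def _effect_candidate_bits(
    fps: Sequence[Fingerprint],
    nbits: int,
    prevalence_range: tuple[float, float] = (0.03, 0.15),
) -> list[int]:
    """Bits eligible to carry effects: library prevalence inside the given
    range, and lowest-indexed representative of their perfect-correlation
    class (one fragment sets several perfectly co-occurring bits across
    radii; attaching the effect to the class representative keeps the
    root-split recovery question well-posed under the lowest-bit tie rule).
    """
    X = fingerprints_to_matrix(fps, nbits)
    prevalence = X.mean(axis=0)
    lo, hi = prevalence_range
    eligible = np.flatnonzero((prevalence >= lo) & (prevalence <= hi))
    seen_columns: set[bytes] = set()
    representatives = []
    for bit in eligible:  # ascending, so first of each class is kept
        column = np.packbits(X[:, bit].astype(np.uint8)).tobytes()
        if column not in seen_columns:
            seen_columns.add(column)
            representatives.append(int(bit))
    return representatives


@dataclass(frozen=True)
class Scenario:
    """A fully materialised synthetic study: molecules, fingerprints,
    ground truth and the simulated training set."""

    molecules: list[Molecule]
    fingerprints: list[Fingerprint]
    ground_truth: GroundTruthModel
    training_set: TrainingSet
    radius: int
    per_compound_noise: Optional[np.ndarray] = None


def scenario_paper_like(
    seed: int,
    n: int = 640,
    nbits: int = 2048,
    radius: int = 2,
    k_effects: int = 3,
    effect_scale: tuple[float, float] = (0.3, 0.6),
    noise_sd: float = 0.08,
    grammar: FragmentGrammar = FragmentGrammar(),
) -> Scenario:
    """The default study conditions: a 640-compound screen over 2048-bit
    ECFP4 fingerprints, 3 sparse effect bits with effect sizes 0.3–0.6,
    and additive noise on the 0.08 scale per target."""
    ss = np.random.SeedSequence(seed)
    s_lib, s_gt, s_noise = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    mols = sample_library(n, grammar, seed=s_lib)
    fps = [ecfp(m, radius=radius, nbits=nbits) for m in mols]
    candidates = _effect_candidate_bits(fps, nbits)
    gt = make_ground_truth(
        nbits,
        k_effects,
        effect_scale=effect_scale,
        noise_sd=noise_sd,
        seed=s_gt,
        candidate_bits=candidates,
    )
    ts = simulate_screen(mols, gt, radius=radius, seed=s_noise, fingerprints=fps)
    return Scenario(
        molecules=mols,
        fingerprints=fps,
        ground_truth=gt,
        training_set=ts,
        radius=radius,
    )


def scenario_signal_free(
    seed: int,
    n: int = 640,
    nbits: int = 2048,
    radius: int = 2,
    noise_sd: float = 0.08,
    grammar: FragmentGrammar = FragmentGrammar(),
) -> Scenario:
    """No effect bits: every expected intensity equals the control (1.0);
    only noise remains.  Used for noise-floor / leakage checks."""
    return scenario_paper_like(
        seed,
        n=n,
        nbits=nbits,
        radius=radius,
        k_effects=0,
        noise_sd=noise_sd,
        grammar=grammar,
    )


def scenario_heteroscedastic(
    seed: int,
    n: int = 640,
    nbits: int = 2048,
    radius: int = 2,
    k_effects: int = 3,
    noise_low: float = 0.02,
    noise_high: float = 0.20,
    grammar: FragmentGrammar = FragmentGrammar(),
) -> Scenario:
    """Two structure-linked noise strata for reliability diagnostics.

    The stratum marker is the fingerprint bit whose library prevalence is
    closest to 0.5 (so roughly half the library is high-noise).  Linking
    noise to structure is what makes tree disagreement informative: a
    compound's tree-sd reflects the target noise of its structural
    neighbours, which is exactly the association the reliability score
    is supposed to capture.
    """
    ss = np.random.SeedSequence(seed)
    s_lib, s_gt, s_noise = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    mols = sample_library(n, grammar, seed=s_lib)
    fps = [ecfp(m, radius=radius, nbits=nbits) for m in mols]
    X = fingerprints_to_matrix(fps, nbits)
    prevalence = X.mean(axis=0)
    stratum_bit = int(np.argmin(np.abs(prevalence - 0.5)))
    per_compound = np.where(X[:, stratum_bit] > 0.5, noise_high, noise_low)
    candidates = _effect_candidate_bits(fps, nbits)
    gt = make_ground_truth(
        nbits,
        k_effects,
        noise_sd=(noise_low, noise_low),
        seed=s_gt,
        candidate_bits=candidates,
    )
    ts = simulate_screen(
        mols,
        gt,
        radius=radius,
        seed=s_noise,
        fingerprints=fps,
        per_compound_noise=per_compound,
    )
    return Scenario(
        molecules=mols,
        fingerprints=fps,
        ground_truth=gt,
        training_set=ts,
        radius=radius,
        per_compound_noise=per_compound,
    )


# ---------------------------------------------------------------------------
# reference drug panel

# Publicly known structures (name, SMILES, approved, in_training).  The
# in_training flag marks drugs present in the original wet screen's
# library (e.g. haloperidol, dexamethasone); the rest emulate the novel
# reference panel plus structurally unrelated distractors.
_REFERENCE_ROWS: tuple[tuple[str, str, bool, bool], ...] = (
    ("dopamine", "NCCc1ccc(O)c(O)c1", True, False),
    ("haloperidol", "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1", True, True),
    ("dexamethasone", "CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO", True, True),
    ("topiramate", "CC1(C)OC2COC3(COS(N)(=O)=O)OC(C)(C)OC3C2O1", True, False),
    ("zanamivir", "CC(=O)NC1C(N=C(N)N)C=C(C(=O)O)OC1C(O)C(O)CO", True, False),
    ("acyclovir", "Nc1nc2c(c(=O)[nH]1)ncn2COCCO", True, False),
    ("progesterone", "CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C", True, False),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", True, False),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", True, False),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1", True, False),
)


def fixture_references(radius: int = 2, nbits: int = 2048) -> ReferenceSet:
    """Packaged panel of known drugs for the grouping stage.

    Includes drugs of the original training library (flagged
    ``in_training``) and a novel panel with distractors; all SMILES parse
    under the chem layer.
    """
    return ReferenceSet.from_smiles(_REFERENCE_ROWS, radius=radius, nbits=nbits)
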