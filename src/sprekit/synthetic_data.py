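"""Synthetic fixtures with known ground truth.

Three generators cover the pipeline end to end without any downloaded
data: saturation-recovery titration tables (mono-exponential build-up plus
Gaussian intensity noise, one duplicate delay per curve, concentrations
0-5 mM), sPRE profiles with implanted accessibility depressions
(mimicking transiently structured regions), and ideal helix/extended
reference conformers for compact-vs-extended accessibility contrasts.
All generators are seed-deterministic and emit exactly the schemas the
rest of the package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coil_ensemble import DEFAULT_CONFIG, _build_chain
from .relaxation_pipeline import DATASET_COLUMNS
from .sequence_profile import SPREProfile
from .structure_model import Conformer, ONE_TO_THREE

__all__ = [
    "TitrationTruth",
    "simulate_recovery_dataset",
    "simulate_truth_profile",
    "build_ideal_helix",
]

#: acquisition design defaults: 10 recovery delays (s) spanning the
#: build-up of a ~1 s^-1 rate, plus one duplicate; 0-5 mM agent
DEFAULT_DELAYS = tuple(np.round(np.geomspace(0.03, 3.0, 10), 4))
DEFAULT_CONCENTRATIONS = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_DUPLICATE_DELAY_INDEX = 4  # mid-range delay recorded twice


@dataclass(frozen=True)
class TitrationTruth:
    """Ground truth of a synthetic titration experiment.

    ``residues`` maps residue_index -> (r1_0 in s^-1, spre in s^-1 mM^-1)
    for one atom role.  Intensities follow I(t) = -A exp(-R1 t) + C with
    R1 = r1_0 + spre * concentration.
    """

    residues: dict
    role: str = "HA"
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    delays: tuple = DEFAULT_DELAYS
    duplicate_delay_index: int = DEFAULT_DUPLICATE_DELAY_INDEX
    noise_sd: float = 0.0  # a.u.
    amplitude: float = 1.0
    plateau: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not self.concentrations or not self.delays:
            raise ValueError("concentrations and delays must be non-empty")
        if 0.0 not in self.concentrations:
            raise ValueError("concentrations must include the 0 mM reference")
        for res, (r1_0, spre) in self.residues.items():
            if spre < 0 or r1_0 <= 0:
                raise ValueError(f"residue {res}: need r1_0 > 0 and spre >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")

    @classmethod
    def random(
        cls,
        n_residues: int,
        seed: int = 0,
        spre_range: tuple[float, float] = (1.0, 6.0),
        r1_0_range: tuple[float, float] = (0.5, 1.5),
        noise_sd: float = 0.01,
        role: str = "HA",
    ) -> "TitrationTruth":
        """Draw per-residue rates uniformly from the given ranges."""
        rng = np.random.default_rng(seed)
        residues = {
            i + 1: (
                float(rng.uniform(*r1_0_range)),
                float(rng.uniform(*spre_range)),
            )
            for i in range(n_residues)
        }
        return cls(residues=residues, role=role, noise_sd=noise_sd, seed=seed)


def simulate_recovery_dataset(truth: TitrationTruth) -> pd.DataFrame:
    """Emit a recovery-intensity table for the relaxation pipeline.

    One curve per residue and concentration: the listed delays plus one
    duplicate of the delay at ``duplicate_delay_index``, intensities from
    the mono-exponential model plus i.i.d. Gaussian noise of SD
    ``noise_sd``.  Deterministic under ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    delays = list(truth.delays) + [truth.delays[truth.duplicate_delay_index]]
    dup_flags = [False] * len(truth.delays) + [True]
    rows = []
    for res in sorted(truth.residues):
        r1_0, spre = truth.residues[res]
        for conc in truth.concentrations:
            r1 = r1_0 + spre * conc
            for t, dup in zip(delays, dup_flags):
                ideal = -truth.amplitude * np.exp(-r1 * t) + truth.plateau
                noisy = ideal + (rng.normal(0.0, truth.noise_sd) if truth.noise_sd else 0.0)
                rows.append({
                    "peak_id": f"res{res}_{truth.role}",
                    "residue_index": res,
                    "residue_name": "XXX",
                    "role": truth.role,
                    "conc_mM": conc,
                    "delay_s": t,
                    "intensity": noisy,
                    "is_duplicate": dup,
                })
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def truth_spre_profile(truth: TitrationTruth, sequence: str | None = None) -> SPREProfile:
    """The ground-truth sPRE values of a titration as an SPREProfile."""
    rows = [
        {"residue_index": res, "role": truth.role, "value": spre, "error": 0.0}
        for res, (_, spre) in sorted(truth.residues.items())
    ]
    seq = sequence or "X" * max(truth.residues)
    return SPREProfile(sequence=seq, data=pd.DataFrame(rows))


def simulate_truth_profile(
    sequence: str,
    base_profile: SPREProfile,
    regions: list[tuple[int, int, float]],
) -> SPREProfile:
    """Implant accessibility depressions into a profile.

    Each region (start, end, f) with 0 < f <= 1 multiplies the values of
    residues start..end (inclusive, 1-based) by f, emulating locally
    reduced solvent accessibility from transient structure; errors are
    left unchanged.
    """
    if base_profile.sequence != sequence:
        raise ValueError("base profile sequence mismatch")
    L = len(sequence)
    data = base_profile.data.copy()
    for start, end, f in regions:
        if not (0.0 < f <= 1.0):
            raise ValueError(f"suppression factor {f} outside (0, 1]")
        if start < 1 or end > L or start > end:
            raise ValueError(f"region ({start}, {end}) outside sequence bounds")
        sel = data["residue_index"].between(start, end)
        data.loc[sel, "value"] *= f
    return SPREProfile(sequence=sequence, data=data)


#: canonical backbone dihedrals (phi, psi) in degrees
_IDEAL_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "extended": (-120.0, 120.0),
}


def build_ideal_helix(sequence: str, kind: str = "helix") -> Conformer:
    """Build an ideal alpha-helical or extended-chain conformer.

    Backbone dihedrals are fixed (helix: phi -57, psi -47; extended:
    phi -120, psi +120; omega 180 throughout); side chains and hydrogens
    are placed exactly as in the coil sampler but without torsion jitter.
    """
    sequence = sequence.upper()
    if kind not in _IDEAL_DIHEDRALS:
        raise ValueError(f"kind must be one of {sorted(_IDEAL_DIHEDRALS)}")
    if len(sequence) < 6:
        raise ValueError("sequence must have at least 6 residues")
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"noncanonical residue letter(s) {bad}")
    phi0, psi0 = _IDEAL_DIHEDRALS[kind]
    L = len(sequence)
    phi = np.full(L, phi0)
    psi = np.full(L, psi0)
    cfg = replace(DEFAULT_CONFIG, chi1_jitter=0.0)
    rng = np.random.default_rng(0)  # unused: no jitter
    return _build_chain(sequence, phi, psi, cfg, rng, label=kind)
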