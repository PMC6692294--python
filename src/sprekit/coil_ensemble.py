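"""Random-coil fragment ensembles and ensemble-averaged sPREs.

The sequence predictor rests on a library of 5-residue fragments embedded
in triple-alanine flanks (``AAA`` + core + ``AAA``).  For each fragment an
ensemble of random-coil conformers is generated, the central residue's
sPRE is back-calculated per conformer, and the ensemble mean/SD is stored.
Because local excluded volume dominates the solvent accessibility of a
disordered chain, the central residue of an 11-mer is a good proxy for the
same residue in the full-length chain.

The conformer generator is a self-contained statistical-coil builder:
backbone dihedrals are drawn from a three-basin Gaussian mixture (PPII,
beta, alpha-R), side chains are placed from ideal residue templates at a
common rotamer with a small chi1 jitter, and clashing conformers are
rejected.  Absolute sPRE magnitudes are therefore generator-dependent;
downstream normalization onto experimental data absorbs the overall scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

import biotite.structure.info as struc_info

from .grid_spre import GridParams, _lattice_geometry, _local_point_spre
from .structure_model import AtomSite, Conformer, ONE_TO_THREE, _role_match

__all__ = [
    "CoilSamplerConfig",
    "FragmentRecord",
    "FragmentLibrary",
    "flank_fragment",
    "sample_coil_conformer",
    "central_spre_samples",
    "build_fragment_record",
    "convergence_curve",
]

# ---------------------------------------------------------------------------
# configuration

#: coil basins: weight, (phi mean, phi sd), (psi mean, psi sd), degrees
_DEFAULT_BASINS = {
    "ppii": (0.45, (-75.0, 15.0), (145.0, 15.0)),
    "beta": (0.30, (-120.0, 25.0), (135.0, 20.0)),
    "alphaR": (0.25, (-63.0, 10.0), (-43.0, 10.0)),
}


@dataclass(frozen=True)
class CoilSamplerConfig:
    """Knobs of the statistical-coil conformer builder.

    basins
        mapping name -> (weight, (phi_mean, phi_sd), (psi_mean, psi_sd));
        weights must sum to 1.
    clash_threshold
        minimum allowed distance (Å) between non-bonded heavy atoms.
    max_attempts
        rejection-sampling budget per conformer.
    build_hydrogens
        include hydrogens (needed for HA/HB/HN back-calculation).
    chi1_jitter
        half-width (degrees) of the uniform jitter applied around the
        canonical chi1 rotamer.
    """

    basins: dict = field(default_factory=lambda: dict(_DEFAULT_BASINS))
    clash_threshold: float = 2.0
    max_attempts: int = 100
    build_hydrogens: bool = True
    chi1_jitter: float = 15.0

    def __post_init__(self):
        total = sum(w for w, _, _ in self.basins.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("basin weights must sum to 1")
        if self.clash_threshold <= 0:
            raise ValueError("clash threshold must be positive")


DEFAULT_CONFIG = CoilSamplerConfig()

# canonical chi1 targets (degrees); gauche- for most side chains
_CHI1_TARGET = {"VAL": 175.0, "THR": 62.0, "SER": 62.0}
_CHI1_DEFAULT = -65.0

# standard peptide geometry (Engh/Huber-style averages)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_B_C_O, _A_CA_C_O = 1.231, 120.4
_B_N_H = 1.02

_BACKBONE_SET = frozenset({"N", "CA", "C", "O", "H", "HA", "HA2", "HA3", "CB"})
_GAMMA_NAMES = ("CG", "CG1", "OG", "OG1", "SG")


# ---------------------------------------------------------------------------
# residue templates (ideal geometry, PDB v3 names)

_TEMPLATE_CACHE: dict[str, dict] = {}


def _residue_template(resname: str) -> dict:
    """Ideal full-atom template of a canonical residue.

    Returns names, elements and coordinates with the free-amino-acid
    artifacts (OXT/HXT, extra amino hydrogens, amide H) stripped; the amide
    hydrogen is rebuilt explicitly during chain assembly.
    """
    tpl = _TEMPLATE_CACHE.get(resname)
    if tpl is not None:
        return tpl
    arr = struc_info.residue(resname)
    drop = {"OXT", "HXT", "H", "H2", "H3", "HN1", "HN2"}
    keep = [i for i, n in enumerate(arr.atom_name) if n not in drop]
    names = [str(arr.atom_name[i]) for i in keep]
    elements = [str(arr.element[i]).capitalize() for i in keep]
    coords = np.asarray(arr.coord, dtype=float)[keep]
    index = {n: i for i, n in enumerate(names)}
    gamma = next((g for g in _GAMMA_NAMES if g in index), None)
    rotating = [
        i for i, n in enumerate(names) if n not in _BACKBONE_SET
    ] if gamma is not None else []
    tpl = {
        "names": names,
        "elements": elements,
        "coords": coords,
        "index": index,
        "gamma": gamma,
        "rotating": np.array(rotating, dtype=int),
    }
    _TEMPLATE_CACHE[resname] = tpl
    return tpl


# ---------------------------------------------------------------------------
# geometry primitives

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d bonded to c."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _rotation_about_axis(axis: np.ndarray, theta_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t with R @ mobile + t ~ target (3 points)."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


# ---------------------------------------------------------------------------
# fragment sequence handling

def flank_fragment(core: str) -> str:
    """Embed a 5-mer in triple-alanine flanks: ``AAA`` + core + ``AAA``."""
    if len(core) != 5:
        raise ValueError(f"fragment core must have exactly 5 residues, got {len(core)}")
    core = core.upper()
    bad = [c for c in core if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"noncanonical residue letter(s) {bad}")
    return "AAA" + core + "AAA"


# ---------------------------------------------------------------------------
# conformer sampling

def _sample_dihedrals(sequence: str, config: CoilSamplerConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    names = list(config.basins)
    weights = np.array([config.basins[k][0] for k in names])
    L = len(sequence)
    phi = np.empty(L)
    psi = np.empty(L)
    for i, letter in enumerate(sequence):
        k = names[rng.choice(len(names), p=weights)]
        _, (pm, ps), (sm, ss) = config.basins[k]
        phi[i] = rng.normal(pm, ps)
        psi[i] = rng.normal(sm, ss)
        if letter == "P":  # pyrrolidine ring pins phi
            phi[i] = rng.normal(-65.0, 8.0)
    return phi, psi


def _build_chain(sequence: str, phi: np.ndarray, psi: np.ndarray,
                 config: CoilSamplerConfig, rng: np.random.Generator,
                 label: str) -> Conformer:
    L = len(sequence)
    resnames = [ONE_TO_THREE[c] for c in sequence]
    # backbone trace
    N = np.empty((L, 3))
    CA = np.empty((L, 3))
    C = np.empty((L, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, L):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi[i])

    atoms: list[AtomSite] = []
    for i in range(L):
        tpl = _residue_template(resnames[i])
        idx = tpl["index"]
        triad_tpl = tpl["coords"][[idx["N"], idx["CA"], idx["C"]]]
        triad = np.stack([N[i], CA[i], C[i]])
        rot, trans = _kabsch(triad_tpl, triad)
        coords = tpl["coords"] @ rot.T + trans
        coords[idx["N"]], coords[idx["CA"]], coords[idx["C"]] = N[i], CA[i], C[i]
        # carbonyl O follows the sampled psi (anti to the next N)
        coords[idx["O"]] = _place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi[i] + 180.0)
        # chi1: canonical rotamer plus jitter
        if tpl["gamma"] is not None:
            target = _CHI1_TARGET.get(resnames[i], _CHI1_DEFAULT)
            target += rng.uniform(-config.chi1_jitter, config.chi1_jitter)
            g = coords[idx[tpl["gamma"]]]
            cb = coords[idx["CB"]]
            current = _dihedral(N[i], CA[i], cb, g)
            rmat = _rotation_about_axis(cb - CA[i], target - current)
            rot_idx = tpl["rotating"]
            coords[rot_idx] = (coords[rot_idx] - cb) @ rmat.T + cb
        for j, name in enumerate(tpl["names"]):
            if not config.build_hydrogens and tpl["elements"][j] == "H":
                continue
            atoms.append(AtomSite(name, tpl["elements"][j], i + 1, resnames[i], coords[j]))
        # rebuild the amide hydrogen in the peptide plane
        if config.build_hydrogens and i > 0 and resnames[i] != "PRO":
            u = N[i] - C[i - 1]
            v = N[i] - CA[i]
            h_dir = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            h_pos = N[i] + _B_N_H * h_dir / np.linalg.norm(h_dir)
            atoms.append(AtomSite("H", "H", i + 1, resnames[i], h_pos))
    return Conformer(sequence, atoms, label=label)


def _has_clash(conf: Conformer, threshold: float) -> bool:
    """True if any non-bonded heavy-atom pair is closer than the threshold.

    Intra-residue pairs are fixed by ideal template geometry and skipped;
    the only inter-residue bonded pair, the peptide C(i)-N(i+1), is exempt.
    """
    heavy = [a for a in conf.atoms if a.element != "H"]
    coords = np.array([a.position for a in heavy])
    res = np.array([a.residue_index for a in heavy])
    names = [a.atom_name for a in heavy]
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    iu, ju = np.triu_indices(len(heavy), k=1)
    inter = res[iu] != res[ju]
    close = d2[iu, ju] < threshold**2
    for k in np.nonzero(inter & close)[0]:
        i, j = iu[k], ju[k]
        lo, hi = (i, j) if res[i] < res[j] else (j, i)
        if res[hi] - res[lo] == 1 and names[lo] == "C" and names[hi] == "N":
            continue
        return True
    return False


def sample_coil_conformer(
    sequence: str,
    config: CoilSamplerConfig = DEFAULT_CONFIG,
    rng_seed: int = 0,
) -> Conformer:
    """Draw one clash-free random-coil conformer of a sequence.

    Backbone phi/psi come from the coil-basin mixture, omega is fixed at
    180° (trans), side chains sit at a canonical chi1 rotamer with jitter.
    Identical seeds give bit-identical coordinates.
    """
    sequence = sequence.upper()
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"noncanonical residue letter(s) {bad}")
    rng = np.random.default_rng(rng_seed)
    for attempt in range(config.max_attempts):
        phi, psi = _sample_dihedrals(sequence, config, rng)
        conf = _build_chain(sequence, phi, psi, config, rng, label=f"seed{rng_seed}")
        if not _has_clash(conf, config.clash_threshold):
            return conf
    raise RuntimeError(
        f"no clash-free conformer of {sequence!r} within {config.max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# ensemble sPRE statistics

def central_spre_samples(
    core: str,
    n: int,
    seed: int,
    grid_params: GridParams | None = None,
    roles: tuple[str, ...] = ("HA", "CA"),
    config: CoilSamplerConfig = DEFAULT_CONFIG,
) -> dict[str, np.ndarray]:
    """Per-conformer central-residue sPRE values for a flanked 5-mer.

    Returns, for each role, an array of length ``n`` holding the sPRE of
    the central residue (atoms of the role averaged within a conformer,
    e.g. glycine HA2/HA3).  Conformer seeds are spawned deterministically
    from ``seed``.
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    grid_params = grid_params or GridParams()
    flanked = flank_fragment(core)
    center = len(flanked) // 2 + 1  # residue 6 of 11, 1-based
    seeds = np.random.SeedSequence(seed).generate_state(n)
    out = {role: np.empty(n) for role in roles}
    for k in range(n):
        conf = sample_coil_conformer(flanked, config, rng_seed=int(seeds[k]))
        coords = conf.coords()
        lo, counts = _lattice_geometry(coords, grid_params)
        tree = cKDTree(coords, balanced_tree=False, compact_nodes=False)
        for role in roles:
            probes = [
                a for a in conf.atoms
                if a.residue_index == center and _role_match(role, a)
            ]
            if not probes:
                raise ValueError(
                    f"role {role!r} absent from the central residue of {flanked!r}"
                )
            vals = [
                _local_point_spre(a.position, lo, counts, tree, grid_params)
                for a in probes
            ]
            out[role][k] = float(np.mean(vals))
    return out


@dataclass(frozen=True)
class FragmentRecord:
    """Ensemble sPRE statistics of the central residue of one flanked 5-mer."""

    core: str
    flanked: str
    stats: dict  # role -> {"mean": float, "sd": float, "n": int}
    seed: int
    grid_params: GridParams

    def __post_init__(self):
        if self.flanked != "AAA" + self.core + "AAA":
            raise ValueError("flanked sequence must be AAA+core+AAA")
        for role, s in self.stats.items():
            if s["n"] < 1 or s["sd"] < 0:
                raise ValueError(f"invalid stats for role {role}")

    def to_dict(self) -> dict:
        gp = self.grid_params
        return {
            "core": self.core,
            "flanked": self.flanked,
            "stats": self.stats,
            "seed": self.seed,
            "grid_params": {
                "spacing": gp.spacing, "margin": gp.margin,
                "probe_radius": gp.probe_radius, "cutoff": gp.cutoff,
                "scale_c": gp.scale_c, "volume_normalized": gp.volume_normalized,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FragmentRecord":
        return cls(
            core=d["core"], flanked=d["flanked"], stats=d["stats"],
            seed=d["seed"], grid_params=GridParams(**d["grid_params"]),
        )


def build_fragment_record(
    core: str,
    n: int = 1500,
    seed: int = 0,
    grid_params: GridParams | None = None,
    roles: tuple[str, ...] = ("HA", "CA"),
    config: CoilSamplerConfig = DEFAULT_CONFIG,
) -> FragmentRecord:
    """Generate an ensemble for a 5-mer core and return its sPRE statistics.

    The default ensemble size of 1500 conformers is the point at which the
    ensemble mean is converged to within a few percent (see
    :func:`convergence_curve`).
    """
    grid_params = grid_params or GridParams()
    samples = central_spre_samples(core, n, seed, grid_params, roles, config)
    stats = {}
    for role, vals in samples.items():
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        stats[role] = {"mean": float(np.mean(vals)), "sd": sd, "n": n}
    return FragmentRecord(
        core=core.upper(), flanked=flank_fragment(core), stats=stats,
        seed=seed, grid_params=grid_params,
    )


def convergence_curve(
    core: str,
    subset_sizes: list[int],
    n_total: int,
    n_repeats: int = 100,
    seed: int = 0,
    grid_params: GridParams | None = None,
    role: str = "CA",
    config: CoilSamplerConfig = DEFAULT_CONFIG,
    master_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Subset-convergence of the ensemble-mean sPRE against a master ensemble.

    One master ensemble of ``n_total`` conformers is generated; for each
    requested size, ``n_repeats`` subsets are drawn without replacement and
    their means compared to the master mean.  Columns: size, mean_of_means,
    sd_of_means, max_rel_dev (max over repeats of |subset mean - master
    mean| / master mean).

    ``master_values`` lets callers reuse precomputed per-conformer values.
    """
    sizes = list(subset_sizes)
    if min(sizes) < 1:
        raise ValueError("subset sizes must be >= 1")
    if max(sizes) > n_total:
        raise ValueError("subset size exceeds the master ensemble")
    if master_values is None:
        master_values = central_spre_samples(
            core, n_total, seed, grid_params, (role,), config
        )[role]
    elif len(master_values) != n_total:
        raise ValueError("master_values length must equal n_total")
    master_mean = float(np.mean(master_values))
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0] ^ 0x5F)
    rows = []
    for size in sizes:
        means = np.array([
            np.mean(rng.choice(master_values, size=size, replace=False))
            for _ in range(n_repeats)
        ])
        rel = np.abs(means - master_mean) / abs(master_mean)
        rows.append({
            "size": size,
            "mean_of_means": float(np.mean(means)),
            "sd_of_means": float(np.std(means, ddof=1)) if n_repeats > 1 else 0.0,
            "max_rel_dev": float(np.max(rel)),
        })
    return pd.DataFrame(rows)


class FragmentLibrary:
    """JSON-backed cache of :class:`FragmentRecord` objects.

    Records are keyed by (core, ensemble size, seed, grid parameters), so a
    library file can be shared across sequences: a full-sequence prediction
    touches one record per distinct 5-mer window.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self._records: dict[str, FragmentRecord] = {}
        if self.path is not None and self.path.exists():
            data = json.loads(self.path.read_text())
            self._records = {k: FragmentRecord.from_dict(v) for k, v in data.items()}

    @staticmethod
    def _key(core: str, n: int, seed: int, grid_params: GridParams) -> str:
        return f"{core.upper()}|n{n}|seed{seed}|{grid_params.cache_key()}"

    def get_or_compute(
        self,
        core: str,
        n: int = 1500,
        seed: int = 0,
        grid_params: GridParams | None = None,
        roles: tuple[str, ...] = ("HA", "CA"),
        config: CoilSamplerConfig = DEFAULT_CONFIG,
    ) -> FragmentRecord:
        grid_params = grid_params or GridParams()
        key = self._key(core, n, seed, grid_params)
        rec = self._records.get(key)
        if rec is not None and all(r in rec.stats for r in roles):
            return rec
        rec = build_fragment_record(core, n, seed, grid_params, roles, config)
        self._records[key] = rec
        self.save()
        return rec

    def save(self) -> None:
        if self.path is None:
            return
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(
            json.dumps({k: r.to_dict() for k, r in self._records.items()}, indent=1)
        )

    def __len__(self) -> int:
        return len(self._records)
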