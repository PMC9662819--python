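"""Synthetic inputs for the hotspot pipeline.

Everything the analysis consumes can be generated here: sort-seq variant
count tables with planted allosterically-dead positions, toy two-chain
Calpha structures with guaranteed short- and long-range contacts, class-
conditional Gaussian feature matrices, and families of homolog feature
matrices whose labels follow a shared rule plus per-protein divergence.

All generators take an explicit integer seed and are bit-reproducible; no
global random state is touched.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CONDITIONS = ("presorted", "sorted_uninduced", "sorted_induced")

COUNT_COLUMNS = [
    "position", "wt_aa", "mut_aa", "sublibrary", "replicate", "condition", "reads",
]


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DmsScenario:
    """Study conditions for a simulated saturation-mutagenesis sort-seq run.

    The defaults emulate a deep screen of a ~120-residue repressor: every
    residue from position 2 mutated to the 19 alternatives, sequenced at a
    mean presorted depth of 100 reads per variant in 3 replicates, with a
    small dropout rate and a low background rate of dead variants away from
    the planted hotspot positions.
    """

    n_positions: int = 120
    planted_hotspots: frozenset = frozenset()
    p_dead_hotspot: float = 0.9
    p_dead_other: float = 0.01
    mean_depth: float = 100.0
    dropout_rate: float = 0.05
    n_replicates: int = 3
    n_sublibraries: int = 2
    nb_dispersion: float = 10.0
    escape_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("p_dead_hotspot", "p_dead_other", "dropout_rate", "escape_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_positions < 2:
            raise ValueError("n_positions must be >= 2")
        object.__setattr__(self, "planted_hotspots", frozenset(self.planted_hotspots))
        bad = [p for p in self.planted_hotspots if not 2 <= p <= self.n_positions]
        if bad:
            raise ValueError(f"planted hotspots outside 2..n_positions: {sorted(bad)}")

    def to_json(self, path):
        d = dataclasses.asdict(self)
        d["planted_hotspots"] = sorted(self.planted_hotspots)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        d["planted_hotspots"] = frozenset(d.get("planted_hotspots", ()))
        return cls(**d)


@dataclass(frozen=True)
class HomologFamilyScenario:
    """A family of homologs sharing a label rule with per-member divergence.

    Labels are assigned by thresholding a noiseless logistic score
    ``X @ coefficients`` at the (1 - prevalence) quantile, so every member
    has exactly the requested hotspot prevalence. Member coefficients are
    the shared rule plus a per-protein Gaussian perturbation of scale
    ``divergence``. With ``perturb_mode='disjoint'`` (default) the
    perturbation acts only on features outside the shared rule's support —
    a conserved core plus lineage-specific determinants, the structure that
    lets pooled training average out idiosyncrasies while fine-tuning can
    still learn them; ``'all'`` perturbs every coefficient.
    """

    n_proteins: int = 4
    n_residues: int = 400
    shared_rule: tuple = (2.0, -1.5, 1.0, 0.8, -0.6)
    divergence: float = 1.5
    prevalence: float = 0.25
    n_features: int = 10
    perturb_mode: str = "disjoint"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")
        if self.n_proteins < 2:
            raise ValueError("n_proteins must be >= 2")
        if self.perturb_mode not in ("disjoint", "all"):
            raise ValueError("perturb_mode must be 'disjoint' or 'all'")


# ---------------------------------------------------------------------------
# Sort-seq count tables
# ---------------------------------------------------------------------------

def _nb_counts(rng, mean, dispersion, size):
    # negative binomial parameterized by mean and dispersion (size) parameter
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_dms_counts(scenario: DmsScenario) -> pd.DataFrame:
    """Simulate a sort-seq variant count table for one protein.

    A variant is either allosterically dead (probability depending on
    whether its position is a planted hotspot) or functional. All present
    variants repress without inducer, so both classes draw full-depth counts
    in the uninduced sorted pool; only dead variants stay repressed under
    induction, so a functional variant's induced-sorted count is a
    Bernoulli thinning (``escape_rate``) of a full-depth draw, emulating the
    rare carry-over of active cells into the low-fluorescence gate.

    Returns a tidy table with one row per
    (position, mutation, replicate, condition); absent (dropout) variants
    are included with zero reads everywhere so the downstream presence
    filter sees the full library design.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    positions = np.arange(2, sc.n_positions + 1)
    n_pos = positions.size

    wt = rng.choice(list(AMINO_ACIDS), size=n_pos)
    hot = np.isin(positions, sorted(sc.planted_hotspots))

    # one row per variant
    var_pos, var_wt, var_mut = [], [], []
    for p, w in zip(positions, wt):
        for m in AMINO_ACIDS:
            if m != w:
                var_pos.append(p)
                var_wt.append(w)
                var_mut.append(m)
    var_pos = np.asarray(var_pos)
    n_var = var_pos.size

    p_dead = np.where(np.isin(var_pos, positions[hot]), sc.p_dead_hotspot, sc.p_dead_other)
    is_dead = rng.random(n_var) < p_dead
    present = rng.random(n_var) >= sc.dropout_rate

    half = (sc.n_positions + 1) // 2
    sublib = np.where(var_pos <= half, 1, 2) if sc.n_sublibraries == 2 else np.ones(n_var, int)

    frames = []
    for rep in range(1, sc.n_replicates + 1):
        presorted = _nb_counts(rng, sc.mean_depth, sc.nb_dispersion, n_var)
        uninduced = _nb_counts(rng, sc.mean_depth, sc.nb_dispersion, n_var)
        induced_full = _nb_counts(rng, sc.mean_depth, sc.nb_dispersion, n_var)
        induced = np.where(
            is_dead, induced_full, rng.binomial(induced_full, sc.escape_rate)
        )
        for cond, reads in (
            ("presorted", presorted),
            ("sorted_uninduced", uninduced),
            ("sorted_induced", induced),
        ):
            frames.append(pd.DataFrame({
                "position": var_pos,
                "wt_aa": var_wt,
                "mut_aa": var_mut,
                "sublibrary": sublib,
                "replicate": rep,
                "condition": cond,
                "reads": np.where(present, reads, 0),
            }))
    table = pd.concat(frames, ignore_index=True)
    table["reads"] = table["reads"].astype(float)
    return table[COUNT_COLUMNS]


# ---------------------------------------------------------------------------
# Toy two-chain structures
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStructure:
    """A toy homodimer: two identical helical-hairpin chains A and B.

    Coordinates are in Angstrom. ``ca`` has shape (2, n_res, 3);
    ``cb`` the same (a dummy side-chain atom); ``b_factor`` (n_res,) is
    shared by the two chains. Ligand and DNA sites are point coordinates.
    """

    ca: np.ndarray
    cb: np.ndarray
    b_factor: np.ndarray
    ligand_sites: np.ndarray
    dna_sites: np.ndarray
    seed: int

    @property
    def n_res(self) -> int:
        return self.ca.shape[1]

    def to_pdb(self, path) -> None:
        """Write the dimer as a standard PDB file (chains A/B, HETATM sites)."""
        lines = []
        serial = 1
        for ci, chain in enumerate("AB"):
            for r in range(self.n_res):
                for name, xyz in (("CA", self.ca[ci, r]), ("CB", self.cb[ci, r])):
                    lines.append(
                        f"ATOM  {serial:5d}  {name:<3s} ALA {chain}{r + 1:4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{self.b_factor[r]:6.2f}          "
                        f"{name[0]:>2s}"
                    )
                    serial += 1
            lines.append(f"TER   {serial:5d}      ALA {chain}{self.n_res:4d}")
            serial += 1
        for resname, sites in (("LIG", self.ligand_sites), ("DNA", self.dna_sites)):
            for k, xyz in enumerate(np.atleast_2d(sites)):
                lines.append(
                    f"HETATM{serial:5d}  C1  {resname} L{k + 1:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"           C"
                )
                serial += 1
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")

    def sites_tsv(self, path) -> None:
        rows = [("ligand", *xyz) for xyz in np.atleast_2d(self.ligand_sites)]
        rows += [("dna", *xyz) for xyz in np.atleast_2d(self.dna_sites)]
        pd.DataFrame(rows, columns=["site_type", "x", "y", "z"]).to_csv(
            path, sep="\t", index=False
        )


def generate_structure(n_res: int, seed: int = 0, jitter: float = 0.15) -> SyntheticStructure:
    """Build a toy dimer of helical-hairpin chains.

    Each chain is an ideal alpha-helical trace (2.3 A radius, 1.5 A rise,
    100 deg/residue) whose axis runs up +z for the first arm, crosses a
    3-residue turn arc, and runs back down -z, 9.5 A away in x. The chain
    is covalently plausible (consecutive Calpha ~3-4.5 A throughout) and
    antiparallel packing of the two arms guarantees contact pairs with
    sequence separation >= 10 for chains of ~25 residues or more; chain B
    is chain A translated in y so the dimer interface also produces
    inter-chain contacts. A small seeded jitter makes distinct seeds
    distinguishable without breaking the designed contact pattern.
    """
    if n_res < 1:
        raise ValueError(f"n_res must be >= 1, got {n_res}")
    rng = np.random.default_rng(seed)
    radius, rise, twist, gap = 2.3, 1.5, np.deg2rad(100.0), 9.5

    if n_res < 12:          # too short to fold back: a single straight helix
        n_turn, arm1 = 0, n_res
    else:
        n_turn = 4
        arm1 = (n_res - n_turn + 1) // 2
    arm2 = n_res - arm1 - n_turn
    z_top = rise * (arm1 - 1)

    ca = np.empty((n_res, 3))
    axis_x = np.empty(n_res)
    for i in range(n_res):
        theta = twist * i
        if i < arm1:
            axis = np.array([0.0, 0.0, rise * i])
            axis_x[i] = 0.0
            ca[i] = axis + [radius * np.cos(theta), radius * np.sin(theta), 0.0]
        elif i < arm1 + n_turn:
            # arc over the top joining the two antiparallel arms, spaced so
            # consecutive Calpha stay at bonded distance
            phi = np.pi * (i - arm1 + 1) / (n_turn + 1)
            ca[i] = [gap / 2 - (gap / 2) * np.cos(phi), 0.0,
                     z_top + 1.0 + 2.0 * np.sin(phi)]
            axis_x[i] = gap / 2
        else:
            j = i - arm1 - n_turn
            axis = np.array([gap, 0.0, rise * (arm2 - 1 - j)])
            axis_x[i] = gap
            ca[i] = axis + [radius * np.cos(theta), radius * np.sin(theta), 0.0]
    ca = ca + rng.normal(0.0, jitter, ca.shape)

    # dummy side-chain atom pointing radially outward from the local axis
    radial = ca - np.column_stack([axis_x, np.zeros(n_res), ca[:, 2]])
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    cb = ca + 1.5 * radial / norms

    chain_b_shift = np.array([0.0, 9.0, 0.0])
    ca2 = np.stack([ca, ca + chain_b_shift])
    cb2 = np.stack([cb, cb + chain_b_shift])

    b_factor = np.clip(25.0 + 10.0 * np.sin(np.arange(n_res) / 3.0)
                       + rng.normal(0.0, 2.0, n_res), 2.0, 99.0)

    # ligand pocket near the C-terminal (second-arm) midpoint of chain A;
    # DNA sites off the N terminus of both chains
    lig_anchor = ca[min(n_res - 1, arm1 + n_turn + arm2 // 2)]
    ligand_sites = lig_anchor + np.array([[0.0, 3.5, 0.0], [1.5, 4.5, 1.0]])
    dna_anchor = ca[0]
    dna_sites = dna_anchor + np.array(
        [[-6.0, 0.0, -4.0], [-6.0, 4.0, -4.0], [-6.0, 9.0, -4.0], [-6.0, 13.0, -4.0]]
    )
    return SyntheticStructure(
        ca=ca2, cb=cb2, b_factor=b_factor,
        ligand_sites=ligand_sites, dna_sites=dna_sites, seed=seed,
    )


# ---------------------------------------------------------------------------
# Feature matrices and homolog families
# ---------------------------------------------------------------------------

def generate_feature_matrix(n_res, labels, effects, sigma=1.0, seed=0,
                            feature_names=None) -> pd.DataFrame:
    """Class-conditional Gaussian feature matrix.

    Column j is Normal(effects[j], sigma[j]) for hotspot rows and
    Normal(0, sigma[j]) for the rest. ``effects``/``sigma`` broadcast over
    the 27 canonical features (or ``feature_names`` if given). Returns a
    DataFrame with a final binary ``label`` column, index = residue 1..n.
    """
    from .structure import FEATURE_NAMES  # canonical registry

    names = list(feature_names) if feature_names is not None else list(FEATURE_NAMES)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (n_res,):
        raise ValueError(f"labels must have length n_res={n_res}, got {labels.shape}")
    effects = np.broadcast_to(np.asarray(effects, dtype=float), (len(names),))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (len(names),))
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, (n_res, len(names))) * sigma + labels[:, None] * effects
    df = pd.DataFrame(X, columns=names, index=pd.RangeIndex(1, n_res + 1, name="residue"))
    df["label"] = labels
    return df


def generate_homolog_family(scenario: HomologFamilyScenario) -> list[pd.DataFrame]:
    """Generate feature matrices for a family of homologs.

    Each member draws iid standard-normal features; its labels are the
    rows whose logistic score under its own coefficients (see
    ``HomologFamilyScenario``) falls in the top ``prevalence`` fraction.
    With divergence 0 every member obeys the same rule; as divergence
    grows past the shared rule's scale, member rules decouple.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    rule = np.zeros(sc.n_features)
    shared = np.asarray(sc.shared_rule, dtype=float)
    rule[: shared.size] = shared
    if sc.perturb_mode == "disjoint":
        perturb_mask = np.arange(sc.n_features) >= shared.size
    else:
        perturb_mask = np.ones(sc.n_features, dtype=bool)
    out = []
    for _ in range(sc.n_proteins):
        coefs = rule.copy()
        coefs[perturb_mask] += rng.normal(0.0, sc.divergence, int(perturb_mask.sum()))
        X = rng.normal(0.0, 1.0, (sc.n_residues, sc.n_features))
        logit = X @ coefs
        thresh = np.quantile(logit, 1.0 - sc.prevalence)
        labels = (logit > thresh).astype(int)
        df = pd.DataFrame(
            X,
            columns=[f"f{j + 1}" for j in range(sc.n_features)],
            index=pd.RangeIndex(1, sc.n_residues + 1, name="residue"),
        )
        df["label"] = labels
        out.append(df)
    return out


def write_counts_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    return table
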