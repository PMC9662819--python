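"""Structure-derived inputs: contact maps, long-range interactions, and the
27-column residue feature matrix.

Structures are homodimers (the functional unit of TetR-family repressors).
The two monomers are combined and renumbered consecutively — chain A keeps
positions 1..L, chain B becomes L+1..2L — so inter-monomer contacts show up
in a single contact map. A long-range interaction (LRI) is a residue pair
within 8 A Calpha-Calpha but separated by >= 10 positions on the renumbered
sequence. LRIs are grouped by k-means on their contact-map coordinates and
the groups ranked by the fraction of unique hotspot residues they contain.

The per-residue feature matrix has three blocks:

* physicochemical (8): table lookups for the wild-type amino acid;
* local (8): atomic density, solvent accessibility, crystallographic
  B-factor computed here; conformational-entropy losses, hydrogen-bond
  counts, frustration index and local structural entropy are imported from
  external tools as pre-computed columns;
* global (11): Gaussian-network-model motional correlations with the
  DNA-/ligand-binding regions and with the rest of the protein, distances
  to DNA/ligand, closeness centrality of the residue contact network,
  distances to the four most prominent centrality peaks, and sequence
  propagation (the largest sequence separation bridged by a <= 5 A
  spatial contact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal
from scipy.linalg import pinvh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .scoring import HotspotSet, load_aa_properties

# ---------------------------------------------------------------------------
# Canonical feature registry
# ---------------------------------------------------------------------------

#: (name, group, default provenance). Imported columns come from external
#: tools (conformational-entropy, hydrogen-bond, frustration and secondary-
#: structure-entropy webservers) and are supplied as a TSV.
FEATURE_REGISTRY = [
    ("molecular_weight", "physicochemical", "computed"),
    ("charge", "physicochemical", "computed"),
    ("hydrophobicity", "physicochemical", "computed"),
    ("aromaticity", "physicochemical", "computed"),
    ("hydrogen_bonding", "physicochemical", "computed"),
    ("polarity", "physicochemical", "computed"),
    ("polarizability", "physicochemical", "computed"),
    ("flexibility", "physicochemical", "computed"),
    ("atomic_density", "local", "computed"),
    ("backbone_entropy_loss", "local", "imported"),
    ("sidechain_entropy_loss", "local", "imported"),
    ("sasa", "local", "computed"),
    ("hydrogen_bond_count", "local", "imported"),
    ("frustration_index", "local", "imported"),
    ("b_factor", "local", "computed"),
    ("local_structural_entropy", "local", "imported"),
    ("corr_dna", "global", "computed"),
    ("corr_ligand", "global", "computed"),
    ("max_corr", "global", "computed"),
    ("dist_dna", "global", "computed"),
    ("dist_ligand", "global", "computed"),
    ("closeness_centrality", "global", "computed"),
    ("dist_peak1", "global", "computed"),
    ("dist_peak2", "global", "computed"),
    ("dist_peak3", "global", "computed"),
    ("dist_peak4", "global", "computed"),
    ("sequence_propagation", "global", "computed"),
]

FEATURE_NAMES = [name for name, _, _ in FEATURE_REGISTRY]
FEATURE_GROUPS = {name: group for name, group, _ in FEATURE_REGISTRY}
IMPORTED_FEATURES = {n for n, _, prov in FEATURE_REGISTRY if prov == "imported"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


# ---------------------------------------------------------------------------
# Dimer structure container
# ---------------------------------------------------------------------------

@dataclass
class Dimer:
    """A renumbered two-chain structure.

    Residue i (1-based) of the renumbered dimer is chain A position i for
    i <= monomer_length and chain B position i - monomer_length otherwise.
    """

    ca: np.ndarray                      # (N, 3) Calpha coordinates
    atoms: list                         # per residue: (k, 3) heavy atoms
    b_factor: np.ndarray                # (N,) mean B-factor per residue
    chain: np.ndarray                   # (N,) chain id per residue
    resseq: np.ndarray                  # (N,) original residue numbers
    sequence: str                       # chain A one-letter sequence
    monomer_length: int
    het_coords: dict                    # HETATM resname -> (m, 3) coords
    bio_structure: object = None        # underlying Bio.PDB structure

    @property
    def n_residues(self) -> int:
        return self.ca.shape[0]

    def to_monomer(self, index: int) -> int:
        return (index - 1) % self.monomer_length + 1


def load_dimer(path) -> Dimer:
    """Parse a PDB dimer, stripping waters and collecting HETATM sites."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("dimer", str(path))
    model = next(structure.get_models())

    chains = []
    het_coords: dict[str, list] = {}
    for chain in model:
        residues = []
        for res in chain:
            hetflag = res.id[0]
            if hetflag == "W":
                continue
            if hetflag.strip():
                het_coords.setdefault(res.resname.strip(), []).extend(
                    atom.coord for atom in res
                )
                continue
            residues.append(res)
        if residues:
            chains.append((chain.id, residues))
    if len(chains) < 2:
        raise ValueError(f"expected a two-chain dimer, found {len(chains)} protein chain(s)")
    chains = chains[:2]

    ca, atoms, bfac, chain_ids, resseq, seq_a = [], [], [], [], [], []
    for ci, (cid, residues) in enumerate(chains):
        for res in residues:
            if "CA" not in res:
                raise ValueError(
                    f"residue {res.resname} {res.id[1]} in chain {cid} has no CA atom"
                )
            ca.append(res["CA"].coord)
            heavy = np.array([a.coord for a in res if a.element != "H"])
            atoms.append(heavy)
            bfac.append(float(np.mean([a.bfactor for a in res])))
            chain_ids.append(cid)
            resseq.append(res.id[1])
            if ci == 0:
                seq_a.append(THREE_TO_ONE.get(res.resname.strip(), "X"))
    monomer_length = len(chains[0][1])
    return Dimer(
        ca=np.asarray(ca, dtype=float),
        atoms=atoms,
        b_factor=np.asarray(bfac),
        chain=np.asarray(chain_ids),
        resseq=np.asarray(resseq),
        sequence="".join(seq_a),
        monomer_length=monomer_length,
        het_coords={k: np.asarray(v, dtype=float) for k, v in het_coords.items()},
        bio_structure=structure,
    )


def residue_heavy_atoms(dimer: Dimer) -> dict:
    """Monomer position -> stacked heavy atoms from both dimer copies."""
    out: dict[int, list] = {}
    for i in range(dimer.n_residues):
        pos = dimer.to_monomer(i + 1)
        out.setdefault(pos, []).append(dimer.atoms[i])
    return {pos: np.vstack(blocks) for pos, blocks in out.items()}


# ---------------------------------------------------------------------------
# Contact maps and long-range interactions
# ---------------------------------------------------------------------------

@dataclass
class ContactMap:
    pairs: pd.DataFrame        # columns i, j (1-based renumbered, i < j), distance
    n_residues: int
    monomer_length: int
    chain: np.ndarray
    cutoff: float


def contact_map(dimer: Dimer, cutoff: float = 8.0) -> ContactMap:
    """All Calpha pairs within ``cutoff`` on the renumbered dimer."""
    tree = cKDTree(dimer.ca)
    pairs = sorted(tree.query_pairs(cutoff))
    rows = [
        (i + 1, j + 1, float(np.linalg.norm(dimer.ca[i] - dimer.ca[j])))
        for i, j in pairs
    ]
    return ContactMap(
        pairs=pd.DataFrame(rows, columns=["i", "j", "distance"]),
        n_residues=dimer.n_residues,
        monomer_length=dimer.monomer_length,
        chain=dimer.chain,
        cutoff=cutoff,
    )


def extract_lri(cmap: ContactMap, min_sep: int = 10) -> set:
    """Contact pairs separated by >= ``min_sep`` renumbered positions."""
    sel = cmap.pairs[(cmap.pairs["j"] - cmap.pairs["i"]).abs() >= min_sep]
    return {(int(i), int(j)) for i, j in zip(sel["i"], sel["j"])}


def cluster_lri(lri: set, k_range=range(1, 16), seed: int = 0, n_init: int = 10,
                k_override: int | None = None):
    """k-means grouping of LRI pairs on their (i, j) contact-map coordinates.

    Returns (assignments, chosen_k, elbow_curve) where ``assignments`` maps
    each pair to a cluster id, ``chosen_k`` is picked as the knee of the
    within-cluster-sum-of-squares curve (maximum second difference, i.e.
    the sharpest drop in marginal gain) unless ``k_override`` is given, and
    ``elbow_curve`` is a DataFrame of (k, wcss).
    """
    from sklearn.cluster import KMeans

    pairs = sorted(lri)
    X = np.asarray(pairs, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if max(ks) > len(pairs):
        raise ValueError(f"k={max(ks)} exceeds number of LRI pairs ({len(pairs)})")

    wcss, models = [], {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        wcss.append(float(km.inertia_))
        models[k] = km
    elbow = pd.DataFrame({"k": ks, "wcss": wcss})

    if k_override is not None:
        if k_override not in models:
            raise ValueError(f"k_override={k_override} not in k_range")
        chosen = int(k_override)
    elif len(ks) >= 3:
        second_diff = np.diff(wcss, 2)  # indexed at ks[1..-2]
        chosen = int(ks[1 + int(np.argmax(second_diff))])
    else:
        chosen = int(ks[int(np.argmin(wcss))])

    labels = models[chosen].predict(X)
    assignments = {pair: int(lab) for pair, lab in zip(pairs, labels)}
    return assignments, chosen, elbow


def rank_clusters(assignments: dict, hotspots, monomer_length: int) -> pd.DataFrame:
    """Rank LRI clusters by percent of unique hotspot residues.

    Dimer indices are collapsed to monomer positions before counting, so a
    residue and its dimer copy are the same site. Rank 1 is the highest
    hotspot fraction; ties break toward the smaller cluster id.
    """
    hotset = set(hotspots.hotspot_positions if isinstance(hotspots, HotspotSet) else hotspots)
    rows = []
    clusters = sorted(set(assignments.values()))
    for cid in clusters:
        members = [p for p, c in assignments.items() if c == cid]
        residues = set()
        for i, j in members:
            residues.add((i - 1) % monomer_length + 1)
            residues.add((j - 1) % monomer_length + 1)
        n_hot = len(residues & hotset)
        frac = 100.0 * n_hot / len(residues) if residues else 0.0
        rows.append((cid, len(members), len(residues), n_hot, frac))
    df = pd.DataFrame(
        rows,
        columns=["cluster", "n_pairs", "n_unique_residues", "n_hotspots",
                 "pct_unique_hotspots"],
    )
    df = df.sort_values(
        ["pct_unique_hotspots", "cluster"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# Physicochemical features (#1-8)
# ---------------------------------------------------------------------------

def physicochemical_features(sequence: str, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wild-type amino-acid property lookups, one row per position."""
    props = table if table is not None else load_aa_properties()
    cols = ["molecular_weight", "charge", "hydrophobicity", "aromaticity",
            "hydrogen_bonding", "polarity", "polarizability", "flexibility"]
    rows = []
    for pos, aa in enumerate(sequence, start=1):
        if aa not in props.index:
            raise ValueError(f"non-canonical amino acid {aa!r} at position {pos}")
        rows.append(props.loc[aa, cols].to_numpy(dtype=float))
    return pd.DataFrame(rows, columns=cols,
                        index=pd.RangeIndex(1, len(sequence) + 1, name="residue"))


# ---------------------------------------------------------------------------
# Local structural features
# ---------------------------------------------------------------------------

def atomic_density(dimer: Dimer, cutoff: float = 5.0) -> np.ndarray:
    """Heavy atoms of *other* residues within ``cutoff`` of any atom of each residue."""
    n = dimer.n_residues
    all_atoms = np.vstack(dimer.atoms)
    owner = np.concatenate([
        np.full(len(a), idx) for idx, a in enumerate(dimer.atoms)
    ])
    tree = cKDTree(all_atoms)
    density = np.zeros(n, dtype=int)
    for idx in range(n):
        neighbor_idx = tree.query_ball_point(dimer.atoms[idx], cutoff)
        near = np.unique(np.concatenate([np.asarray(v, dtype=int) for v in neighbor_idx]))
        density[idx] = int(np.sum(owner[near] != idx))
    return density


def local_features(dimer: Dimer, density_cutoff: float = 5.0,
                   probe_radius: float = 1.4) -> pd.DataFrame:
    """Atomic density, rolling-probe SASA, and mean B-factor per residue.

    Density counts heavy atoms of *other* residues within 5 A of any atom
    of the residue. SASA uses the Shrake-Rupley rolling-probe method
    (probe 1.4 A) on the full dimer; values are summed per residue.
    Rows cover chain A (monomer positions).
    """
    density = atomic_density(dimer, density_cutoff)
    sasa = _shrake_rupley_sasa(dimer, probe_radius)

    L = dimer.monomer_length
    return pd.DataFrame({
        "atomic_density": density[:L],
        "sasa": sasa[:L],
        "b_factor": dimer.b_factor[:L],
    }, index=pd.RangeIndex(1, L + 1, name="residue"))


def _shrake_rupley_sasa(dimer: Dimer, probe_radius: float) -> np.ndarray:
    from Bio.PDB.SASA import ShrakeRupley

    if dimer.bio_structure is None:
        raise ValueError("SASA requires a structure parsed from PDB")
    sr = ShrakeRupley(probe_radius=probe_radius)
    model = next(dimer.bio_structure.get_models())
    sr.compute(model, level="R")
    sasa = []
    idx = 0
    for chain in model:
        for res in chain:
            if res.id[0] != " ":
                continue
            sasa.append(float(res.sasa))
            idx += 1
    if len(sasa) != dimer.n_residues:
        warnings.warn("residue count mismatch between SASA and dimer; truncating")
    return np.asarray(sasa[: dimer.n_residues])


# ---------------------------------------------------------------------------
# Gaussian-network-model correlations
# ---------------------------------------------------------------------------

def gnm_correlation(ca: np.ndarray, cutoff: float = 7.3) -> np.ndarray:
    """Normalized GNM cross-correlation matrix from Calpha coordinates.

    Builds the Kirchhoff (connectivity) matrix at the given cutoff, takes
    its pseudo-inverse (dropping the single zero mode of a connected
    network), and normalizes so the diagonal is 1; entries then lie in
    [-1, 1], from fully anticorrelated to fully correlated motions.
    """
    n = ca.shape[0]
    tree = cKDTree(ca)
    gamma = np.zeros((n, n))
    for i, j in tree.query_pairs(cutoff):
        gamma[i, j] = gamma[j, i] = -1.0
    np.fill_diagonal(gamma, -gamma.sum(axis=1))

    adj = (gamma != 0) & ~np.eye(n, dtype=bool)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"contact network is disconnected ({n_comp} components); "
            f"increase the GNM cutoff (currently {cutoff} A)"
        )
    cov = pinvh(gamma)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def enm_features(dimer: Dimer, dna_sites, ligand_sites, cutoff: float = 7.3,
                 n_site_residues: int = 10, n_top: int = 5) -> pd.DataFrame:
    """Motional-correlation features from a Gaussian network model.

    corr_dna / corr_ligand: the maximum |correlation| of a residue with any
    of the 10 residues closest to the DNA / ligand sites. max_corr: the
    mean of the residue's 5 largest |correlation| values with any other
    residue. Rows cover chain A.
    """
    C = gnm_correlation(dimer.ca, cutoff)
    absC = np.abs(C)
    n = dimer.n_residues

    def site_feature(sites):
        sites = np.atleast_2d(np.asarray(sites, dtype=float))
        if sites.size == 0:
            raise ValueError("empty site coordinate list")
        dmin = np.sqrt(((dimer.ca[:, None, :] - sites[None]) ** 2).sum(-1)).min(axis=1)
        nearest = np.argsort(dmin, kind="stable")[:n_site_residues]
        vals = np.empty(n)
        for i in range(n):
            others = nearest[nearest != i]
            vals[i] = absC[i, others].max() if others.size else 0.0
        return vals

    corr_dna = site_feature(dna_sites)
    corr_ligand = site_feature(ligand_sites)

    off = absC.copy()
    np.fill_diagonal(off, -np.inf)
    top = np.sort(off, axis=1)[:, -n_top:]
    max_corr = np.where(np.isfinite(top), top, 0.0).mean(axis=1)

    L = dimer.monomer_length
    return pd.DataFrame({
        "corr_dna": corr_dna[:L],
        "corr_ligand": corr_ligand[:L],
        "max_corr": max_corr[:L],
    }, index=pd.RangeIndex(1, L + 1, name="residue"))


# ---------------------------------------------------------------------------
# Contact-network centrality
# ---------------------------------------------------------------------------

def residue_contact_graph(dimer: Dimer, cutoff: float = 5.0) -> nx.Graph:
    """Unweighted residue graph: edge when any heavy-atom pair is <= cutoff."""
    all_atoms = np.vstack(dimer.atoms)
    owner = np.concatenate([
        np.full(len(a), idx) for idx, a in enumerate(dimer.atoms)
    ])
    tree = cKDTree(all_atoms)
    G = nx.Graph()
    G.add_nodes_from(range(1, dimer.n_residues + 1))
    for a, b in tree.query_pairs(cutoff):
        ra, rb = int(owner[a]), int(owner[b])
        if ra != rb:
            G.add_edge(ra + 1, rb + 1)
    return G


def centrality_features(dimer: Dimer, graph_cutoff: float = 5.0,
                        peak_residues=None) -> pd.DataFrame:
    """Closeness centrality and Calpha distances to the 4 main centrality peaks.

    The peaks are the four most prominent local maxima of the per-residue
    closeness profile along the renumbered sequence (prominence-ranked;
    peak 1 is the most prominent). Supply ``peak_residues`` (renumbered
    indices) to override automatic detection. Rows cover chain A.
    """
    G = residue_contact_graph(dimer, graph_cutoff)
    clo = nx.closeness_centrality(G)
    profile = np.array([clo[i] for i in range(1, dimer.n_residues + 1)])

    if peak_residues is None:
        locs, props = signal.find_peaks(profile, prominence=0.0)
        if locs.size < 4:
            raise ValueError(
                f"only {locs.size} centrality local maxima found; "
                "supply peak_residues manually"
            )
        order = np.argsort(props["prominences"], kind="stable")[::-1][:4]
        peaks = [int(locs[k]) + 1 for k in order]
    else:
        peaks = [int(p) for p in peak_residues]
        if len(peaks) != 4:
            raise ValueError("peak_residues must list exactly 4 residues")

    L = dimer.monomer_length
    data = {"closeness_centrality": profile[:L]}
    for k, pk in enumerate(peaks, start=1):
        d = np.linalg.norm(dimer.ca - dimer.ca[pk - 1], axis=1)
        data[f"dist_peak{k}"] = d[:L]
    df = pd.DataFrame(data, index=pd.RangeIndex(1, L + 1, name="residue"))
    df.attrs["peak_residues"] = peaks
    return df


# ---------------------------------------------------------------------------
# Geometric features
# ---------------------------------------------------------------------------

def geometry_features(dimer: Dimer, dna_sites, ligand_sites,
                      propagation_cutoff: float = 5.0) -> pd.DataFrame:
    """Distances to DNA/ligand sites and sequence propagation.

    dist_dna / dist_ligand: minimum distance from the residue's Calpha to
    the supplied nucleotide / ligand centers of mass. Sequence propagation
    of residue R: the largest renumbered sequence separation |i - j| over
    residues j whose Calpha is within 5 A of R's. Rows cover chain A.
    """
    def min_dist(sites):
        sites = np.atleast_2d(np.asarray(sites, dtype=float))
        if sites.size == 0:
            raise ValueError("empty site coordinate list")
        return np.sqrt(((dimer.ca[:, None, :] - sites[None]) ** 2).sum(-1)).min(axis=1)

    dist_dna = min_dist(dna_sites)
    dist_ligand = min_dist(ligand_sites)

    n = dimer.n_residues
    tree = cKDTree(dimer.ca)
    prop = np.zeros(n, dtype=int)
    for i, j in tree.query_pairs(propagation_cutoff):
        sep = abs(i - j)
        prop[i] = max(prop[i], sep)
        prop[j] = max(prop[j], sep)

    L = dimer.monomer_length
    return pd.DataFrame({
        "dist_dna": dist_dna[:L],
        "dist_ligand": dist_ligand[:L],
        "sequence_propagation": prop[:L],
    }, index=pd.RangeIndex(1, L + 1, name="residue"))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def compute_structure_features(dimer: Dimer, dna_sites, ligand_sites,
                               gnm_cutoff: float = 7.3,
                               peak_residues=None) -> pd.DataFrame:
    """All locally computable feature columns (22 of 27) for chain A."""
    frames = [
        physicochemical_features(dimer.sequence),
        local_features(dimer),
        enm_features(dimer, dna_sites, ligand_sites, cutoff=gnm_cutoff),
        centrality_features(dimer, peak_residues=peak_residues),
        geometry_features(dimer, dna_sites, ligand_sites),
    ]
    return pd.concat(frames, axis=1)


def assemble_feature_matrix(computed: pd.DataFrame,
                            imported: pd.DataFrame | None,
                            labels) -> pd.DataFrame:
    """Validate and merge computed + imported columns into the 27-feature matrix.

    ``labels`` is a set of hotspot positions (or a HotspotSet). Raises a
    single error listing every unresolved feature name, unexpected column,
    or residue misalignment. The returned DataFrame carries per-column
    provenance in ``attrs['provenance']``.
    """
    hotset = set(labels.hotspot_positions if isinstance(labels, HotspotSet) else labels)
    pieces = {}
    provenance = {}
    problems = []
    sources = [("computed", computed)]
    if imported is not None:
        sources.append(("imported", imported))
    for prov, df in sources:
        for col in df.columns:
            if col not in FEATURE_NAMES:
                problems.append(f"unknown feature column {col!r} ({prov})")
            elif col in pieces:
                problems.append(f"feature {col!r} supplied twice")
            else:
                pieces[col] = df[col]
                provenance[col] = prov
    missing = [n for n in FEATURE_NAMES if n not in pieces]
    if missing:
        problems.append(f"unresolved features: {missing}")
    if not problems:
        index = computed.index
        for col, series in pieces.items():
            if not series.index.equals(index):
                extra = sorted(set(index) - set(series.index))
                problems.append(
                    f"feature {col!r} misaligned; missing residues {extra[:5]}"
                )
            elif series.isna().any():
                bad = series[series.isna()].index.tolist()
                problems.append(f"feature {col!r} has missing values at residues {bad[:5]}")
    if problems:
        raise ValueError("feature matrix assembly failed:\n  " + "\n  ".join(problems))

    matrix = pd.DataFrame({n: pieces[n] for n in FEATURE_NAMES}, index=computed.index)
    matrix["label"] = [int(i in hotset) for i in matrix.index]
    matrix.attrs["provenance"] = provenance
    return matrix


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="residue")


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#").set_index("residue")
    return df
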