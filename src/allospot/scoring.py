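"""Dead-variant calling and positional hotspot scoring for sort-seq DMS data.

The chain implemented here turns replicate read-count tables from a
three-population sort-seq screen (presorted, sorted-uninduced,
sorted-induced) into a per-position weighted score and a quartile-based
hotspot designation:

1. normalize counts within each sub-library and, optionally, across
   proteins with different theoretical library sizes;
2. a variant is *present* if its presorted count reaches the read
   threshold in every replicate;
3. a present variant is *dead in a replicate* if both sorted populations
   reach the threshold in that replicate (it stayed repressed with and
   without inducer); dead calls in 1/2/3 replicates map to confidence
   scores 0/1/2;
4. the positional score is (0*D1 + 1*D2 + 2*D3) / Total, where Dk counts
   variants dead in exactly k replicates and Total counts present
   variants at the position — single-replicate deaths carry zero weight;
5. positions scoring strictly above the third quartile (Q3) of the
   per-protein score distribution are hotspots; residues with any heavy
   atom within 5 A of the ligand can then be excluded, since their dead
   variants plausibly reflect lost ligand affinity rather than broken
   allosteric coupling.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

VARIANT_KEY = ["position", "wt_aa", "mut_aa"]

#: the six per-amino-acid properties compared between dead and not-dead groups
COMPARISON_PROPERTIES = {
    "hydrophilicity": "hydrophilicity",
    "hydrophobicity": "hydrophobicity",
    "polarity": "polarity",
    "mass": "molecular_weight",
    "sasa": "max_sasa",
    "polarizability": "polarizability",
}


def load_aa_properties() -> pd.DataFrame:
    """Bundled per-amino-acid property table, indexed by one-letter code."""
    with importlib.resources.files("allospot.data").joinpath(
        "aa_properties.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#").set_index("aa")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_counts(table: pd.DataFrame, total_target: float = 200_000,
                     library_sizes: dict | None = None) -> pd.DataFrame:
    """Two-step read-count normalization.

    Step 1 rescales each (protein, sublibrary) block so its reads sum to
    ``total_target / n_sublibraries`` across all conditions and replicates.
    Step 2 (only when ``library_sizes`` maps protein -> theoretical mutant
    count) multiplies each protein's reads by its library size over the
    smallest library size among the proteins, so per-variant depths are
    comparable across proteins. Normalized counts stay real-valued; the
    read threshold is applied to these values downstream.
    """
    if table.empty:
        raise ValueError("count table is empty")
    out = table.copy()
    out["reads"] = out["reads"].astype(float)
    has_protein = "protein" in out.columns
    group_cols = (["protein"] if has_protein else []) + ["sublibrary"]

    n_sub = {}
    if has_protein:
        for prot, sub in out.groupby("protein")["sublibrary"].unique().items():
            n_sub[prot] = len(sub)
    else:
        n_sub[None] = out["sublibrary"].nunique()

    for key, block in out.groupby(group_cols):
        total = block["reads"].sum()
        if total == 0:
            raise ValueError(f"sub-library {key} has zero total reads")
        prot = key[0] if has_protein else None
        factor = (total_target / n_sub[prot]) / total
        out.loc[block.index, "reads"] *= factor

    if library_sizes:
        smallest = min(library_sizes.values())
        if smallest <= 0:
            raise ValueError("library sizes must be positive")
        if has_protein:
            for prot, block in out.groupby("protein"):
                out.loc[block.index, "reads"] *= library_sizes[prot] / smallest
        else:
            (only_size,) = library_sizes.values()
            out["reads"] *= only_size / smallest
    return out


# ---------------------------------------------------------------------------
# Presence and dead calling
# ---------------------------------------------------------------------------

def _wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy table to variants x (condition, replicate), zero-filled."""
    wide = table.pivot_table(
        index=VARIANT_KEY, columns=["condition", "replicate"], values="reads",
        aggfunc="sum", fill_value=0.0,
    )
    return wide


def call_presence(table: pd.DataFrame, read_threshold: float = 5) -> pd.DataFrame:
    """Flag variants with >= threshold presorted reads in every replicate."""
    wide = _wide(table)
    pres = wide["presorted"]
    present = (pres >= read_threshold).all(axis=1)
    return present.rename("present").reset_index()


def call_dead(table: pd.DataFrame, read_threshold: float = 5) -> pd.DataFrame:
    """Per-variant dead-replicate counts and confidence scores.

    A present variant is dead in a replicate when both its induced-sorted
    and uninduced-sorted counts reach the threshold. The confidence score
    maps 1/2/3 dead replicates to 0/1/2 and is undefined (NA) otherwise.
    """
    wide = _wide(table)
    present = (wide["presorted"] >= read_threshold).all(axis=1)
    ind = wide["sorted_induced"] >= read_threshold
    unind = wide["sorted_uninduced"] >= read_threshold
    dead_per_rep = (ind & unind)
    n_dead = dead_per_rep.sum(axis=1).where(present, 0)
    calls = pd.DataFrame({
        "present": present,
        "dead_replicates": n_dead.astype(int),
    }, index=wide.index)
    calls["confidence_score"] = (calls["dead_replicates"] - 1).where(
        calls["dead_replicates"] >= 1
    ).astype("Int64")
    return calls.reset_index()


# ---------------------------------------------------------------------------
# Positional scores and hotspot designation
# ---------------------------------------------------------------------------

def position_scores(calls: pd.DataFrame) -> pd.DataFrame:
    """Weighted positional score (0*D1 + 1*D2 + 2*D3) / Total per position.

    Positions where no variant is present are flagged ``no_data`` (score
    NaN) instead of scored 0: absent data is not evidence of mutational
    tolerance, and such positions are excluded from the quartile downstream.
    """
    if calls.empty:
        raise ValueError("no variant calls provided")
    rows = []
    for pos, grp in calls.groupby("position"):
        present = grp[grp["present"]]
        total = len(present)
        d = present["dead_replicates"].value_counts()
        d1, d2, d3 = int(d.get(1, 0)), int(d.get(2, 0)), int(d.get(3, 0))
        score = (0 * d1 + 1 * d2 + 2 * d3) / total if total else np.nan
        rows.append((pos, d1, d2, d3, total, score, total == 0))
    return pd.DataFrame(
        rows, columns=["position", "D1", "D2", "D3", "Total", "weighted_score", "no_data"]
    )


@dataclass
class HotspotSet:
    """Result of the quartile hotspot rule, before/after ligand exclusion."""

    q3_threshold: float
    hotspot_positions: frozenset
    ligand_excluded_positions: frozenset = frozenset()
    post_exclusion_hotspots: frozenset = field(default=None)

    def __post_init__(self):
        if self.post_exclusion_hotspots is None:
            self.post_exclusion_hotspots = frozenset(self.hotspot_positions)


def call_hotspots(scores: pd.DataFrame, percentile_method: str = "linear") -> HotspotSet:
    """Positions with weighted score strictly above Q3 of the distribution.

    Q3 is the 75th percentile over scored (non-``no_data``) positions,
    computed by linear interpolation by default. A degenerate distribution
    (all scores identical) yields an empty hotspot set with a warning.
    """
    valid = scores[~scores["no_data"]]
    if len(valid) < 4:
        raise ValueError("need at least 4 scored positions for a quartile rule")
    vals = valid["weighted_score"].to_numpy(dtype=float)
    q3 = float(np.percentile(vals, 75, method=percentile_method))
    if np.ptp(vals) == 0:
        warnings.warn("all positional scores identical; no hotspots designated")
        return HotspotSet(q3_threshold=q3, hotspot_positions=frozenset())
    hot = frozenset(valid.loc[valid["weighted_score"] > q3, "position"].astype(int))
    return HotspotSet(q3_threshold=q3, hotspot_positions=hot)


def exclude_ligand_contacts(hotspots: HotspotSet, residue_atoms,
                            ligand_coords, cutoff: float = 5.0) -> HotspotSet:
    """Remove hotspot positions with any heavy atom within ``cutoff`` of the ligand.

    ``residue_atoms`` maps monomer position -> (k, 3) array of heavy-atom
    coordinates (both dimer copies stacked if available); ``ligand_coords``
    is an (m, 3) array of ligand heavy-atom or site coordinates. The
    comparison is inclusive: a nearest distance exactly at the cutoff
    excludes the residue.
    """
    lig = np.atleast_2d(np.asarray(ligand_coords, dtype=float))
    if lig.size == 0:
        raise ValueError(
            "no ligand atoms found; supply ligand coordinates via a sidecar site file"
        )
    excluded = set()
    for pos in hotspots.hotspot_positions:
        atoms = np.atleast_2d(np.asarray(residue_atoms[pos], dtype=float))
        dmin = np.sqrt(((atoms[:, None, :] - lig[None, :, :]) ** 2).sum(-1)).min()
        if dmin <= cutoff:
            excluded.add(pos)
    return HotspotSet(
        q3_threshold=hotspots.q3_threshold,
        hotspot_positions=hotspots.hotspot_positions,
        ligand_excluded_positions=frozenset(excluded),
        post_exclusion_hotspots=frozenset(hotspots.hotspot_positions - excluded),
    )


# ---------------------------------------------------------------------------
# Dead vs not-dead mutation-property comparison
# ---------------------------------------------------------------------------

def mutation_property_comparison(calls: pd.DataFrame,
                                 property_table: pd.DataFrame | None = None,
                                 exclude_positions=()) -> dict:
    """Amino-acid enrichment and property means for dead vs not-dead variants.

    The dead group is variants with confidence score >= 1 (dead in at
    least two replicates); the not-dead group is the remaining present
    variants. Ligand-contacting positions should be passed in
    ``exclude_positions``. Reports, per group: the percentage of each final
    mutated amino acid (summing to 100), and mean +/- SEM plus two-sample
    t-test p-values for six physicochemical properties of the mutated
    residue.
    """
    props = property_table if property_table is not None else load_aa_properties()
    present = calls[calls["present"] & ~calls["position"].isin(set(exclude_positions))]
    dead = present[present["dead_replicates"] >= 2]
    not_dead = present[present["dead_replicates"] < 2]
    if dead.empty or not_dead.empty:
        return {"computable": False, "n_dead": len(dead), "n_not_dead": len(not_dead)}

    def pct(group):
        counts = group["mut_aa"].value_counts()
        pcts = (100.0 * counts / counts.sum())
        return {aa: float(pcts.get(aa, 0.0)) for aa in props.index}

    report = {
        "computable": True,
        "n_dead": int(len(dead)),
        "n_not_dead": int(len(not_dead)),
        "dead_percent": pct(dead),
        "not_dead_percent": pct(not_dead),
        "properties": {},
    }
    for name, col in COMPARISON_PROPERTIES.items():
        vd = dead["mut_aa"].map(props[col]).to_numpy(dtype=float)
        vn = not_dead["mut_aa"].map(props[col]).to_numpy(dtype=float)
        t, p = stats.ttest_ind(vd, vn, equal_var=False)
        report["properties"][name] = {
            "dead_mean": float(vd.mean()),
            "dead_sem": float(stats.sem(vd)) if len(vd) > 1 else 0.0,
            "not_dead_mean": float(vn.mean()),
            "not_dead_sem": float(stats.sem(vn)) if len(vn) > 1 else 0.0,
            "t": float(t),
            "p_value": float(p),
        }
    return report


# ---------------------------------------------------------------------------
# Convenience: full scoring chain
# ---------------------------------------------------------------------------

def score_pipeline(table: pd.DataFrame, read_threshold: float = 5,
                   total_target: float = 200_000,
                   library_sizes: dict | None = None,
                   normalize: bool = True) -> tuple[pd.DataFrame, HotspotSet]:
    """Run normalize -> dead calling -> positional scores -> Q3 hotspots."""
    norm = normalize_counts(table, total_target, library_sizes) if normalize else table
    calls = call_dead(norm, read_threshold)
    scores = position_scores(calls)
    return scores, call_hotspots(scores)
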