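"""Bundled study data: the 34-species median-volume table and a synthetic
stand-in chronogram.

The species table ships the published species-median cerebellar, cerebral
and ansiform volumes (mm^3) with their printed MADs and ratio percentages,
plus a curated flag for every ratio cell that recomputes exactly from the
printed medians (cells evidently computed from unrounded volumes are marked
non-recomputable and are never forced to agree).

The real analyses used the 10kTrees consensus chronogram, which is
redistributable only from its source and therefore not bundled; a synthetic
stand-in tree built from approximate literature divergence dates (root age
73 my) supports tree-dependent demonstrations and approximate reproductions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .tree import Phylogeny, read_newick

__all__ = ["StudyFixture", "make_study_fixture", "load_synthetic_consensus_tree",
           "APE_SPECIES", "STREPSIRRHINE_SPECIES"]

#: the seven hominoid (ape) taxa in the sample
APE_SPECIES = (
    "Hylobates_lar", "Pongo_pygmaeus", "Gorilla_gorilla_gorilla", "Gorilla_beringei",
    "Homo_sapiens", "Pan_troglodytes", "Pan_paniscus",
)

#: the nine strepsirrhine taxa (all others are haplorhines)
STREPSIRRHINE_SPECIES = (
    "Galagoides_demidoff", "Loris_tardigradus", "Daubentonia_madagascariensis",
    "Varecia_variegata", "Lemur_catta", "Eulemur_mongoz", "Lepilemur_ruficaudatus",
    "Microcebus_murinus", "Mirza_coquereli",
)


@dataclass
class StudyFixture:
    """The bundled species-median table with its verified-cell annotations."""

    table: pd.DataFrame                # indexed by taxon; volumes in mm^3
    verified_cells: pd.DataFrame       # ratio cells exactly recomputable from medians
    ansiform_species: list[str]
    ape_species: list[str]
    strepsirrhine_species: list[str]

    @property
    def n_species(self) -> int:
        return len(self.table)

    def log_traits(self) -> pd.DataFrame:
        """log10 species-median volumes, plus the rest-of-cerebellum
        (cerebellum minus ansiform) used as a predictor for ansiform
        scaling."""
        out = pd.DataFrame(index=self.table.index)
        for col in ("cerebellum", "cerebrum", "ansiform"):
            out[f"log_{col}"] = np.log10(self.table[col])
        roc = self.table["cerebellum"] - self.table["ansiform"]
        out["log_rest_of_cerebellum"] = np.log10(roc)
        return out


def make_study_fixture() -> StudyFixture:
    """Load the bundled 34-species median table.

    Returns the table indexed by taxon name together with the curated list of
    ratio cells that recompute exactly from the printed medians (the
    verified-cell list), the 13 species with ansiform volumes, and the
    ape/strepsirrhine groupings used by the grade-shift analyses.
    """
    with resources.files("phyloallom.data").joinpath("species_medians.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    df = df.set_index("taxon", drop=False)
    cells = []
    for tag, num, den in (("cbl_cbr", "cerebellum", "cerebrum"),
                          ("ans_cbl", "ansiform", "cerebellum")):
        flag = df[f"{tag}_verified"]
        for taxon in df.index[flag == 1]:
            cells.append({
                "taxon": taxon,
                "ratio": tag,
                "numerator": float(df.loc[taxon, num]),
                "denominator": float(df.loc[taxon, den]),
                "printed_pct": float(df.loc[taxon, f"ratio_{tag}"]),
            })
    ans = df.index[df["ansiform"].notna()].tolist()
    return StudyFixture(
        table=df,
        verified_cells=pd.DataFrame(cells),
        ansiform_species=ans,
        ape_species=list(APE_SPECIES),
        strepsirrhine_species=list(STREPSIRRHINE_SPECIES),
    )


def load_synthetic_consensus_tree() -> Phylogeny:
    """The synthetic stand-in chronogram (root age 73 my; see module docs).

    Provenance is recorded in the returned tree's metadata; anything computed
    on it is an approximate reproduction, not the published analysis.
    """
    path = resources.files("phyloallom.data").joinpath("synthetic_consensus_tree.nwk")
    with resources.as_file(path) as p:
        return read_newick(p, metadata={"provenance": "synthetic stand-in chronogram"})
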