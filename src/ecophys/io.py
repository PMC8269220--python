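"""Readers and writers for the plain-text formats the pipeline exchanges.

Species tables, reaction files, and condition files feed the energetics
module; long-format growth tables feed the growth module; count/length/
library-size/metadata TSVs and Newick trees feed the recruitment module.
"""

from __future__ import annotations

import pandas as pd
import yaml
from skbio import DistanceMatrix, TreeNode

from .growth import GrowthCurve
from .recruit import AbundanceMatrix
from .refdata import T_REF, load_species_table
from .thermo import Reaction, SolutionConditions

__all__ = [
    "read_species_table",
    "read_reaction",
    "read_conditions",
    "read_growth_table",
    "read_abundance_matrix",
    "read_distance_matrix",
    "read_tree",
]

read_species_table = load_species_table


def read_reaction(path) -> Reaction:
    """Read a reaction file: TSV of (species, coefficient) pairs.

    Header comment lines of the form ``# n_electrons: 8`` set the electron
    count; products carry positive and reactants negative coefficients.
    """
    n_electrons = None
    stoich: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("n_electrons"):
                    n_electrons = float(body.split(":", 1)[1])
                continue
            if line.lower().startswith("species\t"):
                continue  # optional header row
            name, coef = line.split("\t")
            stoich[name] = stoich.get(name, 0.0) + float(coef)
    return Reaction(stoich, n_electrons=n_electrons)


def read_conditions(path) -> SolutionConditions:
    """Read a YAML conditions file.

    Keys: ``temperature_C`` (default 25), ``pH`` (default 8.0), optional
    ``ionic_strength`` (mol/kg; computed from molalities when absent), and a
    ``molalities`` mapping of species name → mol/kg.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    temperature = cfg.get("temperature_C")
    temperature = T_REF if temperature is None else 273.15 + float(temperature)
    return SolutionConditions(
        temperature=temperature,
        concentrations={k: float(v) for k, v in (cfg.get("molalities") or {}).items()},
        pH=float(cfg.get("pH", 8.0)),
        ionic_strength=(
            None if cfg.get("ionic_strength") is None else float(cfg["ionic_strength"])
        ),
    )


def read_growth_table(path) -> dict[str, list[GrowthCurve]]:
    """Read a long-format growth table into condition → curves.

    Columns: ``condition`` (optional; one implicit condition if absent),
    ``replicate``, ``time_h``, ``cells_per_ml``.  Separator is inferred from
    the extension (.csv → comma, else tab).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "condition" not in df.columns:
        df = df.assign(condition="all")
    out: dict[str, list[GrowthCurve]] = {}
    for (condition, replicate), grp in df.groupby(["condition", "replicate"]):
        grp = grp.sort_values("time_h")
        out.setdefault(str(condition), []).append(
            GrowthCurve(
                replicate_id=str(replicate),
                times=grp["time_h"].to_numpy(),
                densities=grp["cells_per_ml"].to_numpy(),
            )
        )
    return out


def read_abundance_matrix(
    counts_path,
    lengths_path,
    libsizes_path,
    metadata_path=None,
) -> AbundanceMatrix:
    """Assemble an AbundanceMatrix from TSVs.

    ``counts``: genome × sample table (first column = genome names);
    ``lengths``/``libsizes``: two-column TSVs (name, value); ``metadata``:
    per-sample table keyed by its first column.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    libsizes = pd.read_csv(libsizes_path, sep="\t", index_col=0).iloc[:, 0]
    metadata = (
        pd.read_csv(metadata_path, sep="\t", index_col=0)
        if metadata_path is not None
        else None
    )
    return AbundanceMatrix(
        counts=counts,
        genome_lengths=lengths,
        library_sizes=libsizes,
        sample_metadata=metadata,
    )


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square distance matrix TSV (first column = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def read_tree(path) -> TreeNode:
    """Read a Newick tree."""
    return TreeNode.read(str(path))
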