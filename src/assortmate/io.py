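"""Text-based readers and writers for simulation artifacts.

Tables are tab-separated with a header row; tract exports use BED-like
0-based half-open coordinates; run configuration round-trips through YAML
and run manifests through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import RECORD_COLUMNS, Population, SimConfig, SimulationResult
from .genome import GenomeMap, haplotype_from_switches

TRACT_COLUMNS = [
    "chrom", "start_bp", "end_bp", "source", "haplotype", "individual", "generation",
]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with header, no index, float_format stable across runs."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_summaries(result: SimulationResult, path: str | Path) -> None:
    write_table(result.summaries, path)


def write_records(result: SimulationResult, path: str | Path) -> None:
    df = result.records
    if list(df.columns) != RECORD_COLUMNS:
        df = df[RECORD_COLUMNS]
    write_table(df, path)


def tracts_to_frame(
    pop: Population, generation: int, individuals: np.ndarray | None = None
) -> pd.DataFrame:
    """BED-like tract table (0-based half-open bp) for the selected
    individuals (all by default).  Chromosomes are 0-indexed."""
    idx = (
        np.arange(pop.size, dtype=np.int64)
        if individuals is None
        else np.asarray(individuals, dtype=np.int64)
    )
    rows: list[tuple] = []
    for c, ch in enumerate(pop.genomes.chroms):
        for i in idx:
            for hap in (0, 1):
                for tr in haplotype_from_switches(ch, 2 * int(i) + hap, c):
                    rows.append(
                        (tr.chrom, tr.start_bp, tr.end_bp, tr.source,
                         hap + 1, int(i), generation)
                    )
    return pd.DataFrame(rows, columns=TRACT_COLUMNS)


def write_tracts(
    pop: Population,
    path: str | Path,
    generation: int,
    individuals: np.ndarray | None = None,
) -> None:
    write_table(tracts_to_frame(pop, generation, individuals), path)


def write_tract_lengths(lengths_cm: np.ndarray, path: str | Path) -> None:
    """One tract length (cM) per line under a single-column header."""
    write_table(pd.DataFrame({"length_cm": np.asarray(lengths_cm, float)}), path)


def read_tract_lengths(
    path: str | Path, recomb_rate: float = 1e-8
) -> np.ndarray:
    """Tract lengths in cM from either a single-column length table or the
    BED-like tract export (start_bp/end_bp converted at ``recomb_rate``)."""
    df = read_table(path)
    if {"start_bp", "end_bp"}.issubset(df.columns):
        bp = df["end_bp"].to_numpy(np.int64) - df["start_bp"].to_numpy(np.int64)
        return bp * recomb_rate * 100.0
    col = "length_cm" if "length_cm" in df.columns else df.columns[0]
    return df[col].to_numpy(float)


def config_to_yaml(config: SimConfig, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_from_yaml(path: str | Path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    genome = d.pop("genome", None)
    gmap = None
    if genome is not None:
        gmap = GenomeMap(
            tuple(genome["chrom_lengths_bp"]), genome.get("recomb_rate", 1e-8)
        )
    d["record_tracts_at"] = tuple(d.get("record_tracts_at") or ())
    return SimConfig(genome_map=gmap, **d)


def write_manifest(result: SimulationResult, path: str | Path, **extra) -> None:
    """JSON manifest: config plus headline outcomes of the run."""
    s = result.summaries
    final = s.iloc[-1]
    manifest = {
        "config": result.config.to_dict(),
        "generations_run": int(final["t"]),
        "final_sigma2_x": float(final["sigma2_x"]),
        "final_r_mates": None if np.isnan(final["r_mates"]) else float(final["r_mates"]),
        "final_mean_tract_cm": float(final["mean_tract_cm"]),
        "n_records": int(len(result.records)),
        **extra,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
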