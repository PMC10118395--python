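"""File dialects, run configuration and input cross-checks.

All tables are plain text with ``#`` metadata/comment headers:
pedigree CSV, phenotype TSV, genotype matrix TSV (simple dialect:
``animal_id`` plus one column per marker) or PLINK .raw, a marker map
TSV, and variance components in YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .genotype import GenotypeMatrix
from .mme import VarianceComponents
from .pedigree import Pedigree, PedigreeRecord, sort_and_validate

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pedigree


def write_pedigree(ped: Pedigree, path, comments: list[str] | None = None) -> None:
    """Pedigree CSV: animal_id,sire_id,dam_id,birth_year,sex,path,type."""
    path = Path(path)
    with path.open("w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write("animal_id,sire_id,dam_id,birth_year,sex,path,type\n")
        for i, a in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else ""
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else ""
            fh.write(
                f"{a},{s},{d},{ped.birth_year[i]},{ped.sex[i]},"
                f"{ped.selection_path[i]},{ped.animal_type[i]}\n"
            )


def read_pedigree(path) -> Pedigree:
    """Read the pedigree CSV dialect; empty string means a missing parent."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    expected = ["animal_id", "sire_id", "dam_id", "birth_year", "sex", "path", "type"]
    if list(df.columns) != expected:
        raise DataError(f"pedigree columns {list(df.columns)} != {expected}")
    records = []
    for ln, row in enumerate(df.itertuples(index=False), start=2):
        try:
            year = int(row.birth_year)
        except ValueError as e:
            raise DataError(f"pedigree line {ln}: bad birth year {row.birth_year!r}") from e
        records.append(
            PedigreeRecord(
                animal_id=row.animal_id,
                sire_id=row.sire_id or None,
                dam_id=row.dam_id or None,
                birth_year=year,
                sex=row.sex,
                selection_path=row.path,
                animal_type=row.type,
            )
        )
    return sort_and_validate(records)


# ---------------------------------------------------------------------------
# genotypes


def write_genotypes(geno: GenotypeMatrix, path, map_path=None) -> None:
    """Simple matrix TSV (animal_id + one column per marker, NA missing)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("animal_id\t" + "\t".join(geno.marker_ids) + "\n")
        for i, a in enumerate(geno.animal_ids):
            row = [
                "NA" if np.isnan(v) else (f"{v:g}")
                for v in geno.codes[i]
            ]
            fh.write(a + "\t" + "\t".join(row) + "\n")
    if map_path is not None:
        geno.marker_frame().to_csv(map_path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    mp = pd.read_csv(path, sep="\t", comment="#")
    need = {"marker_id", "chromosome", "position"}
    if not need <= set(mp.columns):
        raise DataError(f"marker map needs columns {sorted(need)}")
    return mp


def read_genotypes(path, map_path=None) -> GenotypeMatrix:
    """Read the simple matrix TSV dialect, with an optional marker map."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    if df.columns[0] != "animal_id":
        raise DataError("genotype TSV must start with an animal_id column")
    marker_ids = list(df.columns[1:])
    codes = df[marker_ids].to_numpy(dtype=float)
    chromosome = np.ones(len(marker_ids), dtype=int)
    position = np.arange(len(marker_ids))
    if map_path is not None:
        mp = read_marker_map(map_path)
        if list(mp["marker_id"]) != marker_ids:
            raise DataError(
                "marker map does not match genotype columns "
                f"({len(mp)} map rows vs {len(marker_ids)} marker columns)"
            )
        chromosome = mp["chromosome"].to_numpy()
        position = mp["position"].to_numpy()
    return GenotypeMatrix(
        animal_ids=df["animal_id"].astype(str).tolist(),
        marker_ids=marker_ids,
        chromosome=chromosome,
        position=position,
        codes=codes,
    )


def read_plink_raw(path, map_path=None) -> GenotypeMatrix:
    """PLINK .raw dialect: FID IID PAT MAT SEX PHENOTYPE then marker columns."""
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != lead:
        raise DataError(f".raw file must start with columns {lead}")
    marker_ids = list(df.columns[6:])
    codes = df[marker_ids].to_numpy(dtype=float)
    chromosome = np.ones(len(marker_ids), dtype=int)
    position = np.arange(len(marker_ids))
    if map_path is not None:
        mp = read_marker_map(map_path)
        if list(mp["marker_id"]) != marker_ids:
            raise DataError("marker map does not match .raw marker columns")
        chromosome = mp["chromosome"].to_numpy()
        position = mp["position"].to_numpy()
    return GenotypeMatrix(
        animal_ids=df["IID"].astype(str).tolist(),
        marker_ids=marker_ids,
        chromosome=chromosome,
        position=position,
        codes=codes,
    )


# ---------------------------------------------------------------------------
# phenotypes and variance components


def write_phenotypes(df: pd.DataFrame, path, comments: list[str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def write_variance_components(vc: VarianceComponents, traits, path) -> None:
    doc = {
        "traits": list(traits),
        "G0": np.asarray(vc.G0).tolist(),
        "R0": np.asarray(vc.R0).tolist(),
        "k": float(vc.k),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_variance_components(path) -> tuple[VarianceComponents, list[str]]:
    doc = yaml.safe_load(Path(path).read_text())
    vc = VarianceComponents(
        G0=np.asarray(doc["G0"], dtype=float),
        R0=np.asarray(doc["R0"], dtype=float),
        k=float(doc["k"]),
    )
    return vc, list(doc["traits"])


# ---------------------------------------------------------------------------
# run configuration and cross-checked reading


@dataclass
class RunConfig:
    """Paths and settings of one evaluation run."""

    pedigree: str = ""
    genotypes: str = ""
    marker_map: str = ""
    phenotypes: str = ""
    variance_components: str = ""
    output_dir: str = "results"
    model_kind: str = "ssnpblup"  # conventional | ssnpblup | ssgblup
    cutoff_year: int | None = None
    base_cohort_year: int | None = None
    tol: float = 1e-10
    max_iter: int = 10000
    seed: int = 1
    group_year_bins: list | None = None

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    bad = set(doc) - known
    if bad:
        raise DataError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(**doc)


def read_inputs(config: RunConfig):
    """Read and cross-check all inputs of a run.

    Ensures every phenotyped and genotyped animal appears in the
    pedigree and that the marker map matches the genotype columns, then
    logs a count summary by birth year and sex.
    """
    ped = read_pedigree(config.pedigree)
    geno = read_genotypes(config.genotypes, config.marker_map or None)
    phen = read_phenotypes(config.phenotypes)
    vc, traits = read_variance_components(config.variance_components)

    orphans = [a for a in phen["animal_id"] if a not in ped.index]
    if orphans:
        raise DataError(f"phenotyped animals not in pedigree: {orphans[:20]}")
    orphans = [a for a in geno.animal_ids if a not in ped.index]
    if orphans:
        raise DataError(f"genotyped animals not in pedigree: {orphans[:20]}")
    for tr in traits:
        if tr not in phen.columns:
            raise DataError(f"phenotype table lacks trait column {tr!r}")

    summary = summarize_population(ped, set(geno.animal_ids), set(phen["animal_id"]))
    log.info("population summary by birth year:\n%s", summary.to_string(index=False))
    return ped, geno, phen, vc, traits


def summarize_population(ped: Pedigree, genotyped: set, phenotyped: set) -> pd.DataFrame:
    """Counts of phenotyped/genotyped cows and steers by birth year."""
    rows = []
    for year in np.unique(ped.birth_year):
        sel = ped.birth_year == year
        idx = np.flatnonzero(sel)
        ids = [ped.ids[i] for i in idx]
        is_cow = ped.animal_type[idx] == "cow"
        is_steer = ped.animal_type[idx] == "steer"
        rows.append(
            {
                "birth_year": int(year),
                "cows_phenotyped": sum(
                    1 for a, c in zip(ids, is_cow) if c and a in phenotyped
                ),
                "steers_phenotyped": sum(
                    1 for a, s in zip(ids, is_steer) if s and a in phenotyped
                ),
                "genotyped_males": sum(
                    1
                    for a, i in zip(ids, idx)
                    if ped.sex[i] == "M" and a in genotyped
                ),
                "genotyped_females": sum(
                    1
                    for a, i in zip(ids, idx)
                    if ped.sex[i] == "F" and a in genotyped
                ),
            }
        )
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path, header_lines: list[str]) -> None:
    """TSV with '#' metadata lines declaring units and provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_bundle(scenario, outdir) -> dict:
    """Write a simulated scenario in the package's file dialects.

    Returns the manifest (also written as JSON) listing files, seed and
    config digest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_pedigree(scenario.pop.ped, outdir / "pedigree.csv", ["synthetic pedigree"])
    write_genotypes(
        scenario.genotypes, outdir / "genotypes.tsv", outdir / "markers.tsv"
    )
    write_phenotypes(
        scenario.phenotypes,
        outdir / "phenotypes.tsv",
        ["one slaughter record per cow/steer; trait units as simulated"],
    )
    write_variance_components(scenario.vc, scenario.config.traits, outdir / "vc.yaml")
    cfg_digest = hashlib.sha256(
        json.dumps(
            {k: str(v) for k, v in asdict(scenario.config).items()}, sort_keys=True
        ).encode()
    ).hexdigest()[:12]
    manifest = {
        "files": ["pedigree.csv", "genotypes.tsv", "markers.tsv", "phenotypes.tsv", "vc.yaml"],
        "seed": scenario.seed,
        "config_digest": cfg_digest,
        "cutoff_year": scenario.cutoff_year,
        "base_cohort_year": scenario.base_cohort_year,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
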