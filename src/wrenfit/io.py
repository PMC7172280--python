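"""Readers and writers for the pipeline's tabular and genotype formats.

All tables are plain CSV with empty fields for missing values.  Genotypes
are written both as a long CSV (id, locus, allele1, allele2) and in
GenePop format with 3-digit allele codes, where "000000" encodes a missing
single-locus genotype.  Years are breeding-season labels (the integer year
the season starts in).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wrenfit.relatedness import GenotypeTable
from wrenfit.simdata import InbreedingEffects, SimConfig, SyntheticDataset

TABLE_FILES = {
    "individuals": "individuals.csv",
    "states": "states.csv",
    "nests": "nests.csv",
    "parentage": "parentage.csv",
    "measurements": "measurements.csv",
    "truth": "truth.csv",
}
GENOTYPE_CSV = "genotypes.csv"
GENEPOP_FILE = "genotypes.gen"


class ValidationError(ValueError):
    """A dataset failed referential-integrity or domain checks."""


@dataclass
class Dataset:
    """Loaded, cross-validated analysis tables (truth may be absent)."""

    individuals: pd.DataFrame
    states: pd.DataFrame
    nests: pd.DataFrame
    parentage: pd.DataFrame
    measurements: pd.DataFrame
    genotypes: GenotypeTable
    truth: pd.DataFrame | None = None

    def validate(self) -> None:
        problems = []
        ids = set(self.individuals["id"])
        if len(ids) != len(self.individuals):
            problems.append("duplicate ids in individuals")
        bad_sex = ~self.individuals["sex"].isin(["male", "female"])
        if bad_sex.any():
            rows = list(self.individuals.index[bad_sex][:5])
            problems.append(f"invalid sex values in individuals rows {rows}")
        for col in ("offspring", "genetic_dam", "genetic_sire", "social_dam", "social_sire"):
            vals = self.parentage[col].dropna()
            missing = ~vals.isin(ids)
            if missing.any():
                rows = list(vals.index[missing][:5])
                problems.append(f"parentage.{col} cites unknown ids at rows {rows}")
        mums = self.nests["mother"].dropna()
        unknown = ~mums.isin(ids)
        if unknown.any():
            problems.append(f"nests.mother cites unknown ids at rows {list(mums.index[unknown][:5])}")
        if not np.issubdtype(self.nests["year"].dtype, np.integer):
            problems.append("nests.year must be integer season labels")
        if problems:
            raise ValidationError("; ".join(problems))


def write_genepop(table: GenotypeTable, path, title: str = "wrenfit genotypes") -> None:
    """Write a GenePop file: 3-digit allele codes, 000000 = missing genotype."""
    lines = [title]
    lines.extend(table.loci)
    lines.append("POP")
    for ind, row in zip(table.ids, table.alleles):
        codes = []
        for a1, a2 in row:
            if a1 == 0 or a2 == 0:
                codes.append("000000")
            else:
                codes.append(f"{a1:03d}{a2:03d}")
        lines.append(f"{ind} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path) -> GenotypeTable:
    """Read a (single-population, one-locus-per-line header) GenePop file."""
    raw = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    if not raw:
        raise ValidationError(f"{path}: empty GenePop file")
    body = raw[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        loci.extend(s.strip() for s in body[i].split(",") if s.strip())
        i += 1
    if i == len(body):
        raise ValidationError(f"{path}: no POP line")
    ids, rows = [], []
    for line in body[i + 1 :]:
        if not line.strip():
            continue
        if line.strip().upper() == "POP":
            raise ValidationError(f"{path}: multiple populations not supported")
        name, _, genos = line.partition(",")
        codes = genos.split()
        if len(codes) != len(loci):
            raise ValidationError(f"{path}: {name.strip()!r} has {len(codes)} genotypes for {len(loci)} loci")
        row = []
        for code in codes:
            if len(code) not in (4, 6):
                raise ValidationError(f"{path}: malformed genotype code {code!r}")
            half = len(code) // 2
            row.append((int(code[:half]), int(code[half:])))
        ids.append(name.strip())
        rows.append(row)
    arr = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(loci), 2), np.int64)
    return GenotypeTable(ids, loci, arr)


def write_dataset(dataset: SyntheticDataset | Dataset, directory) -> dict:
    """Write all tables plus CSV and GenePop genotypes; returns path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for attr, fname in TABLE_FILES.items():
        frame = getattr(dataset, attr, None)
        if frame is None:
            continue
        p = directory / fname
        frame.to_csv(p, index=False)
        paths[attr] = p
    gt = dataset.genotypes
    p = directory / GENOTYPE_CSV
    gt.to_frame().to_csv(p, index=False)
    paths["genotypes"] = p
    gp = directory / GENEPOP_FILE
    write_genepop(gt, gp)
    paths["genepop"] = gp
    return paths


def read_dataset(directory, validate: bool = True) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset`.

    Raises ``ValidationError`` naming any missing file, and (unless
    ``validate=False``) runs referential-integrity checks that report the
    offending rows.
    """
    directory = Path(directory)
    frames = {}
    for attr, fname in TABLE_FILES.items():
        p = directory / fname
        if not p.exists():
            if attr == "truth":
                frames[attr] = None
                continue
            raise ValidationError(f"missing required file: {p}")
        frames[attr] = pd.read_csv(p)
    gpath = directory / GENOTYPE_CSV
    if not gpath.exists():
        raise ValidationError(f"missing required file: {gpath}")
    gframe = pd.read_csv(gpath)
    genotypes = GenotypeTable.from_frame(gframe)
    ds = Dataset(
        individuals=frames["individuals"],
        states=frames["states"],
        nests=frames["nests"],
        parentage=frames["parentage"],
        measurements=frames["measurements"],
        genotypes=genotypes,
        truth=frames["truth"],
    )
    if validate:
        ds.validate()
    return ds


def load_config(path) -> SimConfig:
    """Load a SimConfig from a flat YAML mapping (keys = SimConfig fields;
    inbreeding effects under an ``inbreeding_effects`` sub-mapping)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    eff = raw.pop("inbreeding_effects", None)
    kwargs = dict(raw)
    if "loci" in kwargs:
        kwargs["loci"] = tuple((n, k, tuple(f)) for n, k, f in kwargs["loci"])
    for key in ("survival",):
        if key in kwargs:
            kwargs[key] = tuple(
                ((stage, sex), float(p)) for (stage, sex), p in
                (((item[0][0], item[0][1]), item[1]) for item in kwargs[key])
            )
    if eff is not None:
        kwargs["inbreeding_effects"] = InbreedingEffects(**eff)
    try:
        cfg = SimConfig(**kwargs)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    cfg.validate()
    return cfg
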