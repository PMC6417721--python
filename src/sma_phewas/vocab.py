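"""Vocabularies: named ICD9 code sets, the ICD9→PheWAS-group map, and the
PheWAS-group→physiological-system map.

Three kinds of vocabulary drive the pipeline:

* :class:`CodeSet` — a named set of canonical ICD9 codes used for inclusion
  and exclusion rules (SMA codes, neuromuscular disease/degeneration codes,
  pregnancy codes).  A set matches either exactly or by prefix — prefix
  matching lets a short stem like ``3351`` cover the whole 335.1x family.
* :class:`PhewasMap` — maps each ICD9 code to exactly one PheWAS diagnosis
  group (phecode) with a human-readable label.  Codes absent from the map
  are simply not analyzable phenotypes; they are counted, never dropped
  silently.
* :class:`SystemMap` — maps each PheWAS group to exactly one physiological
  system (Cardiovascular, Gastrointestinal, ...), used by the trajectory
  stage.

These are user inputs in production (the public phecode table is not
redistributed here); :mod:`sma_phewas.fixtures` ships a small stand-in used
by the tests, the docs, and the synthetic study.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .claims_model import normalize_code

__all__ = ["CodeSet", "PhewasMap", "SystemMap", "Vocabulary",
           "load_code_set", "load_phewas_map", "load_system_map", "load_vocabulary"]


@dataclasses.dataclass(frozen=True)
class CodeSet:
    name: str
    codes: frozenset[str]
    match_mode: Literal["exact", "prefix"] = "exact"

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"code set {self.name!r} is empty")
        non_canonical = {c for c in self.codes if normalize_code(c) != c}
        if non_canonical:
            raise ValueError(f"code set {self.name!r} has non-canonical codes: "
                             f"{sorted(non_canonical)[:5]}")

    def contains(self, code: str) -> bool:
        """Membership test for one canonical code (see :meth:`match`)."""
        if not code:
            raise ValueError("empty code")
        if self.match_mode == "exact":
            return code in self.codes
        return any(code.startswith(p) for p in self.codes)

    def match(self, codes: pd.Series) -> pd.Series:
        """Vectorized membership mask over a Series of canonical codes."""
        if self.match_mode == "exact":
            return codes.isin(self.codes)
        mask = np.zeros(len(codes), dtype=bool)
        arr = codes.astype(str)
        for prefix in self.codes:
            mask |= arr.str.startswith(prefix).to_numpy()
        return pd.Series(mask, index=codes.index)

    def digest(self) -> str:
        payload = f"{self.match_mode}:" + ",".join(sorted(self.codes))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PhewasMap:
    """ICD9 → (phewas_code, phenotype_label), flat (no hierarchical rollup).

    Enforces that each ICD9 maps to one group and each group carries one
    label.  :meth:`map_codes` is the vectorized workhorse; it returns the
    mapped group per claim (``NaN`` where unmapped) so callers can report
    ``mapped + unmapped = total``.
    """

    def __init__(self, entries: pd.DataFrame):
        df = entries[["icd9", "phewas_code", "phenotype_label"]].copy()
        df["icd9"] = df["icd9"].map(normalize_code)
        df["phewas_code"] = df["phewas_code"].astype(str).str.strip()
        df = df.drop_duplicates()
        dup = df["icd9"].duplicated()
        if dup.any():
            raise ValueError(f"ICD9 codes mapped to multiple PheWAS groups: "
                             f"{sorted(df.loc[dup, 'icd9'].unique())[:5]}")
        labels = df.drop_duplicates(["phewas_code", "phenotype_label"])
        dup_lab = labels["phewas_code"].duplicated()
        if dup_lab.any():
            raise ValueError(f"PheWAS groups with conflicting labels: "
                             f"{sorted(labels.loc[dup_lab, 'phewas_code'].unique())[:5]}")
        self.entries = df.reset_index(drop=True)
        self._code_of = dict(zip(df["icd9"], df["phewas_code"]))
        self._label_of = dict(zip(df["phewas_code"], df["phenotype_label"]))

    def __len__(self) -> int:
        return len(self._code_of)

    @property
    def phewas_codes(self) -> list[str]:
        return sorted(self._label_of)

    def label(self, phewas_code: str) -> str:
        return self._label_of[phewas_code]

    def lookup(self, icd9: str) -> tuple[str, str] | None:
        """Map one canonical ICD9 code; ``None`` if not an analyzable phenotype."""
        code = self._code_of.get(icd9)
        return None if code is None else (code, self._label_of[code])

    def map_codes(self, icd9: pd.Series) -> pd.Series:
        return icd9.map(self._code_of)

    def icd9_codes_for(self, phewas_code: str) -> list[str]:
        e = self.entries
        return sorted(e.loc[e["phewas_code"] == phewas_code, "icd9"])

    def digest(self) -> str:
        payload = "\n".join(f"{r.icd9}\t{r.phewas_code}\t{r.phenotype_label}"
                            for r in self.entries.sort_values("icd9").itertuples())
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class SystemMap:
    """PheWAS group → physiological system (a function: one system each)."""

    def __init__(self, entries: pd.DataFrame):
        df = entries[["phewas_code", "system_label"]].copy()
        df["phewas_code"] = df["phewas_code"].astype(str).str.strip()
        df = df.drop_duplicates()
        dup = df["phewas_code"].duplicated()
        if dup.any():
            raise ValueError(f"PheWAS groups in multiple systems: "
                             f"{sorted(df.loc[dup, 'phewas_code'].unique())[:5]}")
        self.entries = df.reset_index(drop=True)
        self._system_of = dict(zip(df["phewas_code"], df["system_label"]))

    def system(self, phewas_code: str) -> str | None:
        return self._system_of.get(phewas_code)

    def map_codes(self, phewas_codes: pd.Series) -> pd.Series:
        return phewas_codes.map(self._system_of)

    @property
    def systems(self) -> list[str]:
        return sorted(set(self._system_of.values()))

    def digest(self) -> str:
        payload = "\n".join(f"{r.phewas_code}\t{r.system_label}"
                            for r in self.entries.sort_values("phewas_code").itertuples())
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclasses.dataclass
class Vocabulary:
    """The full vocabulary bundle the pipeline needs."""

    sma: CodeSet
    neuromuscular: CodeSet
    pregnancy: CodeSet
    phewas_map: PhewasMap
    system_map: SystemMap

    def digests(self) -> dict[str, str]:
        return {
            "sma": self.sma.digest(),
            "neuromuscular": self.neuromuscular.digest(),
            "pregnancy": self.pregnancy.digest(),
            "phewas_map": self.phewas_map.digest(),
            "system_map": self.system_map.digest(),
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cs in (self.sma, self.neuromuscular, self.pregnancy):
            with open(out / f"{cs.name}.codes", "w") as fh:
                fh.write(f"# {cs.name} code set (match_mode={cs.match_mode})\n")
                fh.writelines(f"{c}\n" for c in sorted(cs.codes))
        self.phewas_map.entries.sort_values("icd9").to_csv(
            out / "phewas_map.tsv", sep="\t", index=False)
        self.system_map.entries.sort_values("phewas_code").to_csv(
            out / "system_map.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_code_set(path: str | Path, name: str,
                  match_mode: Literal["exact", "prefix"] = "exact") -> CodeSet:
    """Load a code set: one code per line, ``#`` comments, duplicates collapsed."""
    codes = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codes.add(normalize_code(line))
    if not codes:
        raise ValueError(f"{path}: code set {name!r} is empty")
    return CodeSet(name=name, codes=frozenset(codes), match_mode=match_mode)


def load_phewas_map(path: str | Path, sep: str = "\t") -> PhewasMap:
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("icd9", "phewas_code", "phenotype_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return PhewasMap(df)


def load_system_map(path: str | Path, sep: str = "\t") -> SystemMap:
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("phewas_code", "system_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return SystemMap(df)


def load_vocabulary(vocab_dir: str | Path,
                    match_modes: dict[str, str] | None = None) -> Vocabulary:
    """Load the standard bundle from a directory laid out as written by
    :meth:`Vocabulary.write` (``sma.codes``, ``neuromuscular.codes``,
    ``pregnancy.codes``, ``phewas_map.tsv``, ``system_map.tsv``)."""
    d = Path(vocab_dir)
    modes = {"sma": "prefix", "neuromuscular": "prefix", "pregnancy": "prefix"}
    if match_modes:
        modes.update(match_modes)
    return Vocabulary(
        sma=load_code_set(d / "sma.codes", "sma", modes["sma"]),
        neuromuscular=load_code_set(d / "neuromuscular.codes", "neuromuscular",
                                    modes["neuromuscular"]),
        pregnancy=load_code_set(d / "pregnancy.codes", "pregnancy", modes["pregnancy"]),
        phewas_map=load_phewas_map(d / "phewas_map.tsv"),
        system_map=load_system_map(d / "system_map.tsv"),
    )


def map_claim_to_phenotype(claim, pm: PhewasMap) -> tuple[str, str] | None:
    """Map one claim's canonical code to its PheWAS group, or ``None``."""
    return pm.lookup(claim.icd9)
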