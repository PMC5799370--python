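"""Readers and writers for the plain-text input dialects.

Formats: GMT gene sets (set name, description, members, tab-separated);
long-format symptom TSV (disease, symptom, tfidf); comorbidity TSV
(disease_a, disease_b, rr).  Lines starting with ``#`` are comments in all
dialects; headers must be commented.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT-style gene sets: ``name<TAB>description<TAB>gene...``."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one member")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = {f for f in fields[2:] if f}
            if not members:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "", header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for name in sets:
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_symptoms(path: str | Path) -> dict[str, dict[str, float]]:
    """Read long-format symptom scores: ``disease<TAB>symptom<TAB>tfidf``."""
    path = Path(path)
    profiles: dict[str, dict[str, float]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected disease, symptom, tfidf")
            disease, symptom, score = fields[0], fields[1], float(fields[2])
            if score < 0:
                raise ValueError(f"{path}:{lineno}: negative TF-IDF score")
            prof = profiles.setdefault(disease, {})
            if symptom in prof:
                raise ValueError(f"{path}:{lineno}: duplicate symptom {symptom!r} "
                                 f"for {disease!r}")
            prof[symptom] = score
    return profiles


def write_symptoms(profiles: Mapping[str, Mapping[str, float]],
                   path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# disease\tsymptom\ttfidf\n")
        for disease in sorted(profiles):
            for symptom in sorted(profiles[disease]):
                fh.write(f"{disease}\t{symptom}\t{profiles[disease][symptom]:g}\n")


def read_comorbidity(path: str | Path) -> dict[tuple[str, str], float]:
    """Read comorbidity relative risks: ``disease_a<TAB>disease_b<TAB>rr``.

    Pairs are stored unordered; a pair given twice with conflicting values
    is an error.
    """
    path = Path(path)
    rr: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected disease_a, disease_b, rr")
            a, b, val = fields[0], fields[1], float(fields[2])
            if val <= 0:
                raise ValueError(f"{path}:{lineno}: relative risk must be positive")
            key = (a, b) if a <= b else (b, a)
            if key in rr and rr[key] != val:
                raise ValueError(f"{path}:{lineno}: conflicting RR for pair {key}")
            rr[key] = val
    return rr


def write_comorbidity(rr: Mapping[tuple[str, str], float], path: str | Path,
                      header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# disease_a\tdisease_b\trr\n")
        for (a, b) in sorted(rr):
            fh.write(f"{a}\t{b}\t{rr[(a, b)]:g}\n")


def write_table(df: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a results DataFrame as TSV with optional ``#`` header comments."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
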