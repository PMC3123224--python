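"""Parsing of domain-assignment censuses and standard-format round trips.

The input census is a SUPERFAMILY-style table of HMM domain assignments: one
row per assigned domain with a proteome id, a protein id, a SCOP concise
classification string (ccs, e.g. ``c.37.1.12``) and an HMM E-value.  Rows
passing the E-value cutoff are aggregated into genomic abundance counts
``g[fsf, proteome]`` at the fold-superfamily (FSF) level — the first three ccs
fields — so a protein with several hits of one FSF contributes one count per
hit (abundance, not mere occurrence).

Character matrices can be written to and read from PAUP*-compatible NEXUS,
relaxed PHYLIP, and TSV; trees go through newick (via dendropy).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd

from ._tree import Tree
from .character_coding import SYMBOLS, CharacterMatrix

CCS_RE = re.compile(r"^[a-z]\.\d+\.\d+(\.\d+)?$")

SUPERKINGDOMS = ("A", "B", "E")
LIFESTYLES = ("FL", "parasitic", "obligate")


class CensusError(ValueError):
    """Raised for malformed census inputs."""


@dataclass
class AbundanceMatrix:
    """Genomic abundance of FSFs across proteomes.

    ``g`` is an integer DataFrame indexed by FSF id with one column per
    proteome; ``meta`` is indexed by proteome id with ``superkingdom`` and
    ``lifestyle`` columns.
    """

    g: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.g = self.g.astype(np.int64)
        if (self.g.to_numpy() < 0).any():
            raise CensusError("abundance counts must be non-negative")
        if self.g.index.has_duplicates or self.g.columns.has_duplicates:
            raise CensusError("duplicate FSF or proteome ids")
        missing = set(self.g.columns) - set(self.meta.index)
        if missing:
            raise CensusError(f"proteomes without metadata: {sorted(missing)}")
        if self.meta.index.has_duplicates:
            raise CensusError("duplicate metadata rows")
        bad_sk = set(self.meta["superkingdom"]) - set(SUPERKINGDOMS)
        if bad_sk:
            raise CensusError(f"unknown superkingdoms: {sorted(bad_sk)}")
        self.meta = self.meta.loc[list(self.g.columns)]

    @property
    def proteomes(self) -> list[str]:
        return list(self.g.columns)

    @property
    def fsfs(self) -> list[str]:
        return list(self.g.index)

    @property
    def g_max(self) -> int:
        return int(self.g.to_numpy().max()) if self.g.size else 0

    @property
    def total(self) -> int:
        return int(self.g.to_numpy().sum())

    def superkingdom_of(self, proteome: str) -> str:
        return str(self.meta.loc[proteome, "superkingdom"])


def fsf_of_ccs(ccs: str) -> str:
    """Collapse a concise classification string to its parent FSF id."""
    if not CCS_RE.match(ccs):
        raise CensusError(f"malformed ccs {ccs!r}")
    return ".".join(ccs.split(".")[:3])


def read_meta(path: str | Path) -> pd.DataFrame:
    """Read a proteome metadata TSV: proteome_id, superkingdom, lifestyle."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "proteome_id" not in cols:  # headerless file
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, header=None,
            names=["proteome_id", "superkingdom", "lifestyle"],
        )
    else:
        df.columns = cols
    df = df[["proteome_id", "superkingdom", "lifestyle"]]
    bad = set(df["lifestyle"]) - set(LIFESTYLES)
    if bad:
        raise CensusError(f"unknown lifestyles: {sorted(bad)}")
    return df.set_index("proteome_id")


def read_assignments(
    path: str | Path,
    evalue_cutoff: float = 1e-4,
    meta: Optional[pd.DataFrame] = None,
) -> AbundanceMatrix:
    """Parse a domain-assignment TSV into an abundance matrix.

    The table needs at least four tab-separated columns (proteome id, protein
    id, ccs, E-value); a header row is optional, ``#`` lines are comments and
    extra columns are ignored.  Rows with ``evalue > evalue_cutoff`` are
    discarded.  If ``meta`` is None, free-living metadata with superkingdom
    inferred from a ``A|B|E`` prefix of the proteome id is synthesized (the
    convention of the bundled synthetic fixtures).
    """
    if evalue_cutoff <= 0:
        raise CensusError("evalue_cutoff must be positive")
    counts: dict[tuple[str, str], int] = {}
    proteomes: list[str] = []
    fsfs: list[str] = []
    seen_p: set[str] = set()
    seen_f: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise CensusError(f"line {lineno}: expected >=4 tab-separated columns")
            proteome, _protein, ccs, ev = parts[0], parts[1], parts[2], parts[3]
            if lineno == 1 and not _looks_numeric(ev):
                continue  # header row
            try:
                evalue = float(ev)
            except ValueError:
                raise CensusError(f"line {lineno}: unparseable E-value {ev!r}")
            if evalue < 0:
                raise CensusError(f"line {lineno}: negative E-value")
            try:
                fsf = fsf_of_ccs(ccs)
            except CensusError as exc:
                raise CensusError(f"line {lineno}: {exc}")
            if evalue > evalue_cutoff:
                continue
            if proteome not in seen_p:
                seen_p.add(proteome)
                proteomes.append(proteome)
            if fsf not in seen_f:
                seen_f.add(fsf)
                fsfs.append(fsf)
            counts[(fsf, proteome)] = counts.get((fsf, proteome), 0) + 1
    if not counts:
        raise CensusError("no assignments passed the E-value cutoff")
    g = pd.DataFrame(0, index=fsfs, columns=proteomes, dtype=np.int64)
    for (fsf, proteome), n in counts.items():
        g.loc[fsf, proteome] = n
    if meta is None:
        meta = _default_meta(proteomes)
    return AbundanceMatrix(g=g, meta=meta)


def _looks_numeric(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def _default_meta(proteomes: Iterable[str]) -> pd.DataFrame:
    rows = []
    for p in proteomes:
        sk = p[0] if p[:1] in SUPERKINGDOMS else "B"
        rows.append({"proteome_id": p, "superkingdom": sk, "lifestyle": "FL"})
    return pd.DataFrame(rows).set_index("proteome_id")


def filter_proteomes(
    m: AbundanceMatrix,
    keep_lifestyles: set[str] | Iterable[str] = ("FL",),
    balanced: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[AbundanceMatrix, list[str]]:
    """Restrict to selected lifestyles (optionally balanced per superkingdom).

    Returns the filtered matrix together with the list of FSFs dropped
    because they became all-zero (absent from every retained proteome).
    ``balanced`` subsamples that many proteomes from each superkingdom,
    reproducibly under ``seed``.
    """
    keep_lifestyles = set(keep_lifestyles)
    bad = keep_lifestyles - set(LIFESTYLES)
    if bad:
        raise CensusError(f"unknown lifestyles: {sorted(bad)}")
    keep = [p for p in m.proteomes if m.meta.loc[p, "lifestyle"] in keep_lifestyles]
    if balanced is not None:
        rng = np.random.default_rng(seed)
        chosen: list[str] = []
        for sk in SUPERKINGDOMS:
            pool = [p for p in keep if m.meta.loc[p, "superkingdom"] == sk]
            if len(pool) < balanced:
                raise CensusError(
                    f"superkingdom {sk}: only {len(pool)} proteomes available, "
                    f"cannot sample {balanced}"
                )
            idx = rng.choice(len(pool), size=balanced, replace=False)
            chosen.extend(pool[i] for i in sorted(idx))
        keep = [p for p in m.proteomes if p in set(chosen)]
    g = m.g[keep]
    zero = g.sum(axis=1) == 0
    dropped = [f for f, z in zero.items() if z]
    g = g.loc[~zero]
    return AbundanceMatrix(g=g, meta=m.meta.loc[keep].copy()), dropped


# ---------------------------------------------------------------------------
# Character-matrix formats
# ---------------------------------------------------------------------------


def write_matrix(cm: CharacterMatrix, path: str | Path, format: str = "nexus") -> None:
    """Write a character matrix as NEXUS, relaxed PHYLIP, or TSV.

    The NEXUS output is PAUP*-oriented: it declares the ``0~9A~N`` symbol
    alphabet, marks all characters ordered in an ASSUMPTIONS block, and states
    the hypothetical-ancestor polarity in a comment.
    """
    fmt = format.lower()
    path = Path(path)
    if fmt == "nexus":
        path.write_text(_to_nexus(cm))
    elif fmt in ("phylip", "phylip-relaxed"):
        path.write_text(_to_phylip(cm))
    elif fmt == "tsv":
        df = pd.DataFrame(cm.states, index=cm.taxa, columns=cm.characters)
        with open(path, "w") as fh:
            fh.write(f"# polarity={cm.polarity} n_states={cm.n_states}\n")
            df.to_csv(fh, sep="\t", index_label="taxon")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_matrix(path: str | Path, format: str = "nexus") -> CharacterMatrix:
    fmt = format.lower()
    text = Path(path).read_text()
    if fmt == "nexus":
        return _from_nexus(text)
    if fmt in ("phylip", "phylip-relaxed"):
        return _from_phylip(text)
    if fmt == "tsv":
        return _from_tsv(path)
    raise ValueError(f"unknown format {format!r}")


def _to_nexus(cm: CharacterMatrix) -> str:
    nt, nc = cm.shape
    lines = [
        "#NEXUS",
        f"[polarity={cm.polarity} n_states={cm.n_states}]",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={nt} NCHAR={nc};",
        f'  FORMAT SYMBOLS="{cm.symbols}";',
        "  MATRIX",
    ]
    quoted = [_quote(t) for t in cm.taxa]
    width = max((len(q) for q in quoted), default=0) + 2
    for i, q in enumerate(quoted):
        lines.append(f"    {q:<{width}}{cm.encode_row(i)}")
    lines += [
        "  ;",
        "END;",
        "BEGIN ASSUMPTIONS;",
        "  OPTIONS DEFTYPE=ORD;",
        "END;",
        "BEGIN CHARACTERS_INFO;",
        "[" + " ".join(cm.characters) + "]",
        "END;",
        "",
    ]
    return "\n".join(lines)


def _quote(label: str) -> str:
    return f"'{label}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", label) else label


def _from_nexus(text: str) -> CharacterMatrix:
    polarity = "zero_ancestral"
    n_states = 24
    meta = re.search(r"\[polarity=(\w+) n_states=(\d+)\]", text)
    if meta:
        polarity, n_states = meta.group(1), int(meta.group(2))
    block = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not block:
        raise CensusError("no MATRIX block found in NEXUS input")
    taxa: list[str] = []
    rows: list[np.ndarray] = []
    for line in block.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        m = re.match(r"^(?:'([^']+)'|(\S+))\s+(\S+)$", line)
        if not m:
            raise CensusError(f"unparseable NEXUS matrix row: {line!r}")
        taxa.append(m.group(1) or m.group(2))
        rows.append(CharacterMatrix.decode_symbols(m.group(3), n_states))
    chars_block = re.search(r"BEGIN CHARACTERS_INFO;\s*\[(.*?)\]", text, re.S)
    if chars_block and chars_block.group(1).split():
        characters = chars_block.group(1).split()
    else:
        characters = [f"char{i}" for i in range(len(rows[0]))]
    return CharacterMatrix(taxa, characters, np.vstack(rows), polarity, n_states)


def _to_phylip(cm: CharacterMatrix) -> str:
    # relaxed PHYLIP: names must not contain whitespace, so spaces become
    # underscores (round trips are exact only for whitespace-free names)
    nt, nc = cm.shape
    lines = [f"{nt} {nc}"]
    for i, taxon in enumerate(cm.taxa):
        name = re.sub(r"\s+", "_", taxon)
        lines.append(f"{name}  {cm.encode_row(i)}")
    return "\n".join(lines) + "\n"


def _from_phylip(text: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    nt, nc = (int(x) for x in lines[0].split()[:2])
    taxa, rows = [], []
    for ln in lines[1 : nt + 1]:
        name, seq = ln.split(None, 1)
        taxa.append(name)
        rows.append(CharacterMatrix.decode_symbols(seq.strip()))
    characters = [f"char{i}" for i in range(nc)]
    return CharacterMatrix(taxa, characters, np.vstack(rows))


def _from_tsv(path: str | Path) -> CharacterMatrix:
    polarity, n_states = "zero_ancestral", 24
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"polarity=(\w+) n_states=(\d+)", first)
            if m:
                polarity, n_states = m.group(1), int(m.group(2))
        else:  # pragma: no cover - tolerate missing header comment
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return CharacterMatrix(
        [str(t) for t in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=np.int16),
        polarity,
        n_states,
    )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def write_tree(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def read_tree(path: str | Path) -> Tree:
    dt = dendropy.Tree.get(path=str(path), schema="newick")
    return Tree.from_newick(dt.as_string(schema="newick").replace("[&U]", "").strip())
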