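"""Reading, validation and curation of qHTS tables, descriptor matrices and LD50 data.

The in-memory model has three pieces:

* :class:`ConcentrationResponseProfile` — one compound's viability curve in one
  cell line, 14 responses at strictly increasing micromolar concentrations.
  Responses are stored as percent **loss** of viability (0 = baseline, 100 =
  complete loss); input files whose responses are signed percent change versus
  vehicle can be negated on read.
* :class:`DescriptorMatrix` — a compound x descriptor table, each column tagged
  ``chemical`` or ``biological``, with optional range-scaling state.
* :class:`ToxicityRecord` — a compound with its -log10 LD50 (mol/kg) and the
  toxicity class derived from it.

All tabular IO is plain CSV/TSV through pandas so that every intermediate of
the pipeline is inspectable and replayable.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ASSAY_PANEL",
    "CompoundEntry",
    "ConcentrationResponseProfile",
    "CurationError",
    "DescriptorMatrix",
    "FormatError",
    "ToxicityRecord",
    "curate_compounds",
    "default_concentration_grid",
    "read_descriptor_matrix",
    "read_ld50_table",
    "read_qhts_table",
    "read_structures",
    "write_descriptor_matrix",
    "write_qhts_table",
]

#: The 13 cell-viability assay cell lines of the screening panel.
ASSAY_PANEL: tuple[str, ...] = (
    "BJ",          # human foreskin fibroblast
    "Jurkat",      # human acute T-cell leukemia
    "HEK293",      # human embryonic kidney
    "HepG2",       # human hepatoma
    "MRC-5",       # human lung fibroblast
    "SK-N-SH",     # human neuroblastoma
    "N2a",         # mouse neuroblastoma
    "NIH3T3",      # mouse embryonic fibroblast
    "HUV-EC-C",    # human vascular endothelium
    "H-4-II-E",    # rat hepatoma
    "SH-SY-5Y",    # human neuroblastoma
    "RPTC",        # rat renal proximal tubule
    "Mesenchymal", # human renal glomeruli
)

#: Elements whose presence marks a structure as organometallic.  Metalloids
#: (B, Si, As, Te ...) are deliberately not listed.
DEFAULT_METAL_ELEMENTS: frozenset[str] = frozenset(
    {
        "Li", "Na", "K", "Rb", "Cs", "Be", "Mg", "Ca", "Sr", "Ba",
        "Al", "Ga", "In", "Tl", "Sn", "Pb", "Bi",
        "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
        "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
        "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
        "La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho",
        "Er", "Tm", "Yb", "Lu", "Th", "U",
    }
)


class FormatError(ValueError):
    """A file does not have the layout the reader requires."""


class CurationError(ValueError):
    """Input rows violate a uniqueness or consistency rule."""


def default_concentration_grid(n_points: int = 14, c_min: float = 0.006, c_max: float = 92.0) -> np.ndarray:
    """Geometric concentration series (uM) spanning the assay range.

    The screen tested 14 concentrations between 0.006 and 92 uM; the exact
    spacing is taken as geometric, which is the standard qHTS dilution design.
    """
    return np.geomspace(c_min, c_max, n_points)


@dataclass(frozen=True)
class ConcentrationResponseProfile:
    """One compound's 14-point viability curve in one cell line.

    ``responses`` are percent loss of viability: 0 means no effect, 100 means
    complete loss of viability.
    """

    compound_id: str
    cell_line: str
    concentrations: tuple[float, ...]
    responses: tuple[float, ...]

    def __post_init__(self) -> None:
        conc = tuple(float(c) for c in self.concentrations)
        resp = tuple(float(r) for r in self.responses)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if len(conc) != len(resp):
            raise ValueError(
                f"{self.compound_id}/{self.cell_line}: {len(conc)} concentrations "
                f"but {len(resp)} responses"
            )
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError(
                f"{self.compound_id}/{self.cell_line}: concentrations must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.concentrations)

    def with_responses(self, responses: Sequence[float]) -> "ConcentrationResponseProfile":
        return ConcentrationResponseProfile(
            self.compound_id, self.cell_line, self.concentrations, tuple(responses)
        )


@dataclass(frozen=True)
class ToxicityRecord:
    """A compound with its acute-toxicity potency on the -log10 mol/kg scale."""

    compound_id: str
    neg_log_ld50: float
    tox_class: str  # "toxic" | "nontoxic" | "marginal"

    @classmethod
    def from_potency(cls, compound_id: str, neg_log_ld50: float) -> "ToxicityRecord":
        from .dataset import assign_toxicity_class  # local import avoids a cycle

        return cls(compound_id, float(neg_log_ld50), assign_toxicity_class(neg_log_ld50))


class DescriptorMatrix:
    """Dense compound x descriptor table with per-column origin tags.

    Parameters
    ----------
    data:
        DataFrame indexed by compound id, one numeric column per descriptor.
    origin:
        Either a single tag applied to every column or a mapping from
        descriptor name to ``"chemical"`` / ``"biological"``.
    scaled:
        True once every column has been range scaled into [0, 1].
    scaling_params:
        ``(min, max)`` Series pair recorded when scaling was fit, used to
        transform external compounds with the *training* ranges only.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        origin: str | Mapping[str, str] = "chemical",
        scaled: bool = False,
        scaling_params: tuple[pd.Series, pd.Series] | None = None,
        flags: Mapping[str, list[str]] | None = None,
    ) -> None:
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if data.isna().any().any():
            bad = data.columns[data.isna().any()].tolist()
            raise ValueError(f"missing values in descriptors: {bad}")
        self.data = data.astype(float)
        if isinstance(origin, str):
            self.origin = {name: origin for name in data.columns}
        else:
            self.origin = dict(origin)
            missing = set(data.columns) - set(self.origin)
            if missing:
                raise ValueError(f"columns without origin tag: {sorted(missing)}")
        self.scaled = bool(scaled)
        self.scaling_params = scaling_params
        self.flags = dict(flags or {})

    # -- basic views ---------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_compounds(self, ids: Sequence[str]) -> "DescriptorMatrix":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"compounds not in matrix: {missing[:5]}")
        return DescriptorMatrix(
            self.data.loc[list(ids)],
            origin=self.origin,
            scaled=self.scaled,
            scaling_params=self.scaling_params,
            flags={k: v for k, v in self.flags.items() if k in set(ids)},
        )

    def subset_descriptors(self, names: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(
            self.data[list(names)],
            origin={n: self.origin[n] for n in names},
            scaled=self.scaled,
            flags=self.flags,
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_CONC_HEADER = re.compile(r"^c[_ ]?([0-9.eE+-]+)$")


def _parse_concentration_header(name: str) -> float | None:
    m = _CONC_HEADER.match(name.strip())
    if m:
        try:
            return float(m.group(1))
        except ValueError:
            return None
    try:
        return float(name)
    except ValueError:
        return None


def _read_table(path, delimiter: str | None, encoding: str | None) -> pd.DataFrame:
    sep = delimiter
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep, encoding=encoding, dtype={"compound_id": str})


def read_qhts_table(
    path,
    panel: Sequence[str] = ASSAY_PANEL,
    negate_responses: bool = False,
    delimiter: str | None = None,
    encoding: str | None = None,
) -> tuple[list[ConcentrationResponseProfile], list[dict]]:
    """Read a qHTS table into profiles.

    The file must have columns ``compound_id``, ``cell_line`` and one column
    per assay concentration, headed either by the bare micromolar value or by
    ``c_<value>`` (e.g. ``c_0.006`` ... ``c_92``).  Concentration columns may
    appear in any order; profiles always come back sorted by concentration.

    Set ``negate_responses=True`` for files that store signed percent change
    in viability (negative = cell death); the canonical in-memory convention
    is percent *loss* of viability.

    Returns
    -------
    (profiles, rejected):
        ``rejected`` is a machine-readable report, one dict per dropped row
        (keys ``compound_id``, ``cell_line``, ``reason``).
    """
    df = _read_table(path, delimiter, encoding)
    required = {"compound_id", "cell_line"}
    if not required.issubset(df.columns):
        raise FormatError(f"missing required columns: {sorted(required - set(df.columns))}")

    conc_cols: list[tuple[float, str]] = []
    for col in df.columns:
        if col in required:
            continue
        c = _parse_concentration_header(col)
        if c is not None:
            conc_cols.append((c, col))
    if not conc_cols:
        raise FormatError("no concentration-labeled response columns found")
    conc_cols.sort(key=lambda t: t[0])
    concentrations = tuple(c for c, _ in conc_cols)
    ordered_cols = [name for _, name in conc_cols]

    pair_counts = df.groupby(["compound_id", "cell_line"]).size()
    dupes = pair_counts[pair_counts > 1]
    if len(dupes) > 0:
        raise CurationError(
            "duplicate (compound, cell line) rows: "
            + ", ".join(f"{c}/{l}" for c, l in dupes.index)
        )

    panel_set = set(panel)
    profiles: list[ConcentrationResponseProfile] = []
    rejected: list[dict] = []
    for _, row in df.iterrows():
        cid, line = str(row["compound_id"]), str(row["cell_line"])
        if line not in panel_set:
            rejected.append({"compound_id": cid, "cell_line": line, "reason": "unknown cell line"})
            continue
        try:
            resp = np.asarray([float(row[c]) for c in ordered_cols], dtype=float)
        except (TypeError, ValueError):
            rejected.append({"compound_id": cid, "cell_line": line, "reason": "unparseable response"})
            continue
        if not np.all(np.isfinite(resp)):
            rejected.append({"compound_id": cid, "cell_line": line, "reason": "non-finite response"})
            continue
        if negate_responses:
            resp = -resp
        profiles.append(
            ConcentrationResponseProfile(cid, line, concentrations, tuple(resp))
        )
    return profiles, rejected


def write_qhts_table(profiles: Iterable[ConcentrationResponseProfile], path, delimiter: str = "\t") -> None:
    """Write profiles back to the tabular layout :func:`read_qhts_table` accepts."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    grid = profiles[0].concentrations
    for p in profiles:
        if p.concentrations != grid:
            raise ValueError("profiles share one file only if they share one concentration grid")
    cols = [f"c_{c:g}" for c in grid]
    rows = [
        {"compound_id": p.compound_id, "cell_line": p.cell_line, **dict(zip(cols, p.responses))}
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def read_descriptor_matrix(
    path,
    origin: str = "chemical",
    delimiter: str | None = None,
    encoding: str | None = None,
) -> DescriptorMatrix:
    """Read a compound x descriptor TSV/CSV (first column ``compound_id``)."""
    df = _read_table(path, delimiter, encoding)
    if "compound_id" not in df.columns:
        raise FormatError("descriptor matrix must have a compound_id column")
    df = df.set_index("compound_id")
    return DescriptorMatrix(df, origin=origin)


def write_descriptor_matrix(matrix: DescriptorMatrix, path, delimiter: str = "\t") -> None:
    matrix.data.rename_axis("compound_id").to_csv(path, sep=delimiter)


def read_ld50_table(path, delimiter: str | None = None, encoding: str | None = None) -> list[ToxicityRecord]:
    """Read a (compound_id, neg_log_ld50) table into classified records."""
    df = _read_table(path, delimiter, encoding)
    if not {"compound_id", "neg_log_ld50"}.issubset(df.columns):
        raise FormatError("LD50 table needs columns compound_id, neg_log_ld50")
    records = []
    for _, row in df.iterrows():
        records.append(ToxicityRecord.from_potency(str(row["compound_id"]), float(row["neg_log_ld50"])))
    return records


def write_ld50_table(records: Iterable[ToxicityRecord], path, delimiter: str = "\t") -> None:
    rows = [
        {"compound_id": r.compound_id, "neg_log_ld50": r.neg_log_ld50, "tox_class": r.tox_class}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Structure-aware curation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundEntry:
    compound_id: str
    structure: str | None = None  # SMILES; None when no structure is available


@dataclass(frozen=True)
class RemovedEntry:
    entry: CompoundEntry
    reason: str


def _mol_from_smiles(smiles: str):
    try:
        from rdkit import Chem
        from rdkit import RDLogger

        RDLogger.DisableLog("rdApp.error")
    except ImportError:  # pragma: no cover - rdkit is an optional extra
        return None, False
    return Chem.MolFromSmiles(smiles), True


_ELEMENT_TOKEN = re.compile(r"[A-Z][a-z]?")


def _structure_checks(smiles: str, metals: frozenset[str]) -> str | None:
    """Return a removal reason for a structure, or None if it passes.

    Uses RDKit when available; otherwise falls back to an element-token scan of
    the SMILES string, which covers the same three rules (mixture, inorganic,
    organometallic) for well-formed SMILES.
    """
    if not smiles:
        return "undefined structure"
    mol, have_rdkit = _mol_from_smiles(smiles)
    if have_rdkit:
        if mol is None:
            return "undefined structure"
        from rdkit import Chem

        if len(Chem.GetMolFrags(mol)) > 1:
            return "mixture"
        symbols = {atom.GetSymbol() for atom in mol.GetAtoms()}
        if "C" not in symbols:
            return "inorganic"
        if symbols & metals:
            return "organometallic"
        return None

    # Fallback: token scan.
    if not smiles or not re.fullmatch(r"[A-Za-z0-9@+\-\[\]()=#$:./\\%]+", smiles):
        return "undefined structure"
    if "." in smiles:
        return "mixture"
    tokens = set(_ELEMENT_TOKEN.findall(smiles))
    has_carbon = bool({"C", "c"} & set(re.findall(r"C(?![a-z])|c", smiles)))
    if not has_carbon:
        return "inorganic"
    if tokens & metals:
        return "organometallic"
    return None


def read_structures(path, fmt: str | None = None, encoding: str | None = None) -> list[CompoundEntry]:
    """Read compound structures from a SMILES list or an SDF file.

    SMILES files (``.smi``/``.smiles``, or ``fmt="smiles"``) hold one
    ``id<TAB>smiles`` pair per line (a single column is treated as a SMILES
    with itself as id).  SDF reading requires RDKit; the record id is taken
    from the molecule title, falling back to ``mol<i>``.
    """
    name = str(path).lower()
    if fmt is None:
        fmt = "sdf" if name.endswith(".sdf") else "smiles"
    entries: list[CompoundEntry] = []
    if fmt == "smiles":
        with open(path, encoding=encoding) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) >= 2:
                    entries.append(CompoundEntry(parts[0], parts[1]))
                else:
                    entries.append(CompoundEntry(parts[0], parts[0]))
        return entries
    if fmt == "sdf":
        try:
            from rdkit import Chem
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading SDF structures requires rdkit") from exc
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                # empty structure string -> removed as "undefined structure"
                entries.append(CompoundEntry(f"mol{i}", ""))
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
            entries.append(CompoundEntry(cid, Chem.MolToSmiles(mol)))
        return entries
    raise ValueError(f"unknown structure format: {fmt}")


def curate_compounds(
    entries: Sequence[CompoundEntry | tuple],
    metal_elements: frozenset[str] = DEFAULT_METAL_ELEMENTS,
) -> tuple[list[CompoundEntry], list[RemovedEntry]]:
    """Apply the standard library-curation rules.

    Removes, in order of precedence per entry: exact duplicate compound ids
    (the first occurrence is kept), entries whose structure does not parse
    ("undefined structure"), multi-component structures ("mixture"),
    carbon-free structures ("inorganic") and metal-containing structures
    ("organometallic").  Entries without a structure are only subject to the
    duplicate rule.  Idempotent: re-curating the kept list removes nothing.
    """
    norm: list[CompoundEntry] = [
        e if isinstance(e, CompoundEntry) else CompoundEntry(*e) for e in entries
    ]
    kept: list[CompoundEntry] = []
    removed: list[RemovedEntry] = []
    seen: set[str] = set()
    for entry in norm:
        if entry.compound_id in seen:
            removed.append(RemovedEntry(entry, "duplicate"))
            continue
        if entry.structure is not None:
            reason = _structure_checks(entry.structure, metal_elements)
            if reason is not None:
                removed.append(RemovedEntry(entry, reason))
                continue
        seen.add(entry.compound_id)
        kept.append(entry)
    return kept, removed
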