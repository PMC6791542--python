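"""Readers and writers for cavity-set formats.

The package's interchange format is a small XML dialect, one document per
protein:

.. code-block:: xml

    <protein id="1a4u">
      <cavity id="cleft1" type="CLEFT" volume="450.000">
        <sphere x="1.000" y="2.000" z="3.000" r="1.400"/>
      </cavity>
    </protein>

``type`` is one of CLEFT/TUNNEL/PORE/NOTYPE (absent means NOTYPE) and
``volume`` (Å³) is optional.  Coordinates are written with 3 decimals and
stable attribute order, so writing is deterministic.

Method outputs arrive in several shapes and each gets a reader:

* one PQR file of Voronoi balls per pocket (Fpocket-style);
* a single PDB-like file of pseudo-atoms for all cavities, grouped by
  residue number (GHECOM-style) or ungrouped (KVFinder/GaussianFinder-
  style soups, which then go through DBSCAN clustering);
* tunnel/pore XML whose profile nodes carry X/Y/Z/Radius attributes
  (Mole-style);
* script files with embedded dummy-atom records grouped into numbered
  clusters with optional volume annotations (PDBsum-cleft-style).

Grid-based methods emit pseudo-atoms whose radius is half the grid
spacing; their readers therefore take an explicit default radius rather
than guessing a spacing.

Every reader preserves input order of cavities and atoms, and reports
skipped records through a :class:`ParseReport`.
"""

from __future__ import annotations

import csv
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

from .core import Cavity, CavitySet, CavityType, ClassificationCounts, PseudoAtom

__all__ = [
    "ParseReport",
    "CavityXMLError",
    "read_cavity_xml",
    "write_cavity_xml",
    "read_pqr_pockets",
    "read_pseudo_atom_pdb",
    "read_mole_xml",
    "read_embedded_cleft_records",
    "merge_cavity_sets",
    "write_counts_csv",
]


class CavityXMLError(ValueError):
    """Malformed cavity XML (names the offending element where possible)."""


@dataclass
class ParseReport:
    """Bookkeeping for a parse: how many candidate records were used,
    how many skipped, and why."""

    records_read: int = 0
    records_skipped: int = 0
    warnings: list[str] = field(default_factory=list)

    def skip(self, message: str) -> None:
        self.records_skipped += 1
        self.warnings.append(message)


# ---------------------------------------------------------------------------
# cavity-set XML dialect
# ---------------------------------------------------------------------------

def read_cavity_xml(stream: Union[IO[str], str], source: str = "xml") -> CavitySet:
    """Parse a cavity-set XML document into a :class:`CavitySet`.

    Cavity and sphere order is preserved.  A cavity without a ``type``
    attribute is NOTYPE.  Malformed XML, missing coordinates or a
    non-positive radius raise :class:`CavityXMLError`.
    """
    text = stream if isinstance(stream, str) else stream.read()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise CavityXMLError(f"malformed XML: {exc}") from exc
    if root.tag != "protein":
        raise CavityXMLError(f"expected <protein> root, found <{root.tag}>")
    protein_id = root.get("id")
    if not protein_id:
        raise CavityXMLError("<protein> element lacks an id attribute")

    cavities: list[Cavity] = []
    for k, cav_el in enumerate(root.findall("cavity")):
        cav_id = cav_el.get("id") or f"cavity{k + 1}"
        type_attr = cav_el.get("type", "NOTYPE").upper()
        try:
            cav_type = CavityType[type_attr]
        except KeyError:
            raise CavityXMLError(
                f"cavity {cav_id!r}: unknown type {type_attr!r}"
            ) from None
        volume: Optional[float] = None
        if cav_el.get("volume") is not None:
            volume = float(cav_el.get("volume"))  # type: ignore[arg-type]
        atoms: list[PseudoAtom] = []
        for s, sph in enumerate(cav_el.findall("sphere")):
            try:
                x, y, z = (float(sph.get(a)) for a in ("x", "y", "z"))  # type: ignore[arg-type]
                r = float(sph.get("r"))  # type: ignore[arg-type]
            except (TypeError, ValueError) as exc:
                raise CavityXMLError(
                    f"cavity {cav_id!r}, sphere {s + 1}: bad or missing "
                    f"coordinate/radius attribute"
                ) from exc
            if r <= 0:
                raise CavityXMLError(
                    f"cavity {cav_id!r}, sphere {s + 1}: non-positive radius {r}"
                )
            atoms.append(PseudoAtom((x, y, z), r))
        if not atoms:
            raise CavityXMLError(f"cavity {cav_id!r} has no spheres")
        cavities.append(Cavity(id=cav_id, type=cav_type, atoms=atoms, volume=volume))
    return CavitySet(protein_id=protein_id, source=source, cavities=cavities)


def write_cavity_xml(cavity_set: CavitySet, stream: IO[str]) -> None:
    """Serialize a :class:`CavitySet` to the XML dialect.

    Output is byte-deterministic: fixed attribute order, 3-decimal
    coordinates, the ``volume`` attribute only when set.
    """
    lines = [f'<protein id="{cavity_set.protein_id}">']
    for cav in cavity_set:
        vol = f' volume="{cav.volume:.3f}"' if cav.volume is not None else ""
        lines.append(f'  <cavity id="{cav.id}" type="{cav.type.value}"{vol}>')
        for a in cav.atoms:
            x, y, z = a.center
            lines.append(
                f'    <sphere x="{x:.3f}" y="{y:.3f}" z="{z:.3f}" r="{a.radius:.3f}"/>'
            )
        lines.append("  </cavity>")
    lines.append("</protein>")
    stream.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PQR pockets (one file per pocket, Voronoi balls of variable radius)
# ---------------------------------------------------------------------------

def read_pqr_pockets(
    files: Sequence[Union[IO[str], str]],
    protein_id: str,
    source: str = "pqr",
) -> tuple[CavitySet, ParseReport]:
    """Read one pocket per PQR stream into a NOTYPE :class:`CavitySet`.

    PQR layout: ATOM/HETATM records whose last two whitespace-separated
    numeric fields are charge and radius, preceded by x, y, z.  Records
    with fewer than two trailing numeric fields or a non-positive radius
    are skipped with a warning; an empty file is an error.  Pockets are
    labelled "pocket1", "pocket2", … in input order.
    """
    report = ParseReport()
    cavities: list[Cavity] = []
    for k, f in enumerate(files):
        text = f if isinstance(f, str) else f.read()
        atoms: list[PseudoAtom] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            numeric: list[float] = []
            for tok in fields[1:]:
                try:
                    numeric.append(float(tok))
                except ValueError:
                    continue
            # need x, y, z, charge, radius at the tail
            if len(numeric) < 5:
                report.skip(f"pocket {k + 1} line {lineno}: too few numeric fields")
                continue
            x, y, z = numeric[-5:-2]
            radius = numeric[-1]
            if radius <= 0:
                report.skip(f"pocket {k + 1} line {lineno}: non-positive radius")
                continue
            serial = int(numeric[0]) if numeric and numeric[0].is_integer() else None
            atoms.append(PseudoAtom((x, y, z), radius, serial=serial))
            report.records_read += 1
        if not atoms:
            raise ValueError(f"pocket file {k + 1} contains no usable records")
        cavities.append(
            Cavity(id=f"pocket{k + 1}", type=CavityType.NOTYPE, atoms=atoms)
        )
    return CavitySet(protein_id=protein_id, source=source, cavities=cavities), report


# ---------------------------------------------------------------------------
# PDB-like pseudo-atom records (fixed column, whitespace fallback)
# ---------------------------------------------------------------------------

_FLOAT_RE = re.compile(r"^[+-]?\d+\.\d*$|^[+-]?\.\d+$")


def _parse_pdb_like_line(line: str):
    """Extract (serial, resnum, x, y, z, extra_floats) from an ATOM/HETATM
    line.  Fixed PDB columns first (coords in 1-based columns 31–54),
    whitespace tokens as fallback for "PDB-like" files that drift off the
    grid.  Returns None when no coordinates can be recovered."""
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        serial = int(line[6:11]) if line[6:11].strip() else None
        resnum = int(line[22:26]) if line[22:26].strip() else None
        extra = [float(t) for t in line[54:].split() if _FLOAT_RE.match(t)]
        return serial, resnum, x, y, z, extra
    except (ValueError, IndexError):
        pass
    tokens = line.split()
    decimals = [i for i, t in enumerate(tokens) if _FLOAT_RE.match(t)]
    if len(decimals) < 3:
        return None
    i0 = decimals[0]
    if decimals[1] != i0 + 1 or decimals[2] != i0 + 2:
        return None
    x, y, z = (float(tokens[i]) for i in (i0, i0 + 1, i0 + 2))
    ints = []
    for t in tokens[1:i0]:
        try:
            ints.append(int(t))
        except ValueError:
            continue
    serial = ints[0] if ints else None
    resnum = ints[-1] if len(ints) > 1 else None
    extra = [float(t) for t in tokens[i0 + 3:] if _FLOAT_RE.match(t)]
    return serial, resnum, x, y, z, extra


def read_pseudo_atom_pdb(
    stream: Union[IO[str], str],
    default_radius: float,
    cavity_id_from_residue: bool,
    protein_id: str = "unknown",
    source: str = "pdb",
) -> tuple[Union[CavitySet, list[PseudoAtom]], ParseReport]:
    """Read pseudo-atoms from a single PDB-like file.

    With ``cavity_id_from_residue`` records are grouped into cavities by
    residue sequence number (grid methods that label each cavity as a
    residue); otherwise a flat pseudo-atom list is returned for the
    clustering stage.  When a record carries no radius field the atom gets
    ``default_radius`` — for grid methods, half the grid spacing.
    Unparseable coordinates are skipped with a warning; a file with zero
    usable records is an error.
    """
    if default_radius <= 0:
        raise ValueError("default_radius must be positive")
    text = stream if isinstance(stream, str) else stream.read()
    report = ParseReport()
    parsed: list[tuple[Optional[int], PseudoAtom]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        rec = _parse_pdb_like_line(line)
        if rec is None:
            report.skip(f"line {lineno}: unparseable coordinates")
            continue
        serial, resnum, x, y, z, extra = rec
        radius = next((v for v in extra if v > 0), default_radius)
        parsed.append((resnum, PseudoAtom((x, y, z), radius, serial=serial)))
        report.records_read += 1
    if not parsed:
        raise ValueError("no usable pseudo-atom records found")

    if not cavity_id_from_residue:
        return [a for _, a in parsed], report

    groups: dict[Optional[int], list[PseudoAtom]] = {}
    order: list[Optional[int]] = []
    for resnum, atom in parsed:
        if resnum not in groups:
            groups[resnum] = []
            order.append(resnum)
        groups[resnum].append(atom)
    cavities = [
        Cavity(id=f"cavity{k + 1}", type=CavityType.NOTYPE, atoms=groups[res])
        for k, res in enumerate(order)
    ]
    return (
        CavitySet(protein_id=protein_id, source=source, cavities=cavities),
        report,
    )


# ---------------------------------------------------------------------------
# tunnel/pore XML (Mole-style)
# ---------------------------------------------------------------------------

def _attr_ci(el: ET.Element, name: str) -> Optional[str]:
    for k, v in el.attrib.items():
        if k.lower() == name.lower():
            return v
    return None


def read_mole_xml(
    stream: Union[IO[str], str],
    protein_id: str,
    source: str = "mole",
) -> tuple[CavitySet, ParseReport]:
    """Extract tunnels and pores from tunnel/pore profile XML.

    One cavity per ``tunnel`` or ``pore`` element (tag match is
    case-insensitive), typed from the enclosing tag; spheres come from
    descendant nodes carrying X/Y/Z/Radius attributes (case-insensitive).
    Only geometry is read — every other piece of content is ignored.
    Nodes missing a radius are skipped with a warning; a document with no
    tunnel/pore elements is an error.
    """
    text = stream if isinstance(stream, str) else stream.read()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise CavityXMLError(f"malformed XML: {exc}") from exc

    report = ParseReport()
    cavities: list[Cavity] = []
    counters = {"tunnel": 0, "pore": 0}
    for el in root.iter():
        tag = el.tag.rsplit("}", 1)[-1].lower()
        if tag not in ("tunnel", "pore"):
            continue
        counters[tag] += 1
        cav_type = CavityType.TUNNEL if tag == "tunnel" else CavityType.PORE
        atoms: list[PseudoAtom] = []
        for node in el.iter():
            if node is el:
                continue
            xs, ys, zs = (_attr_ci(node, a) for a in ("x", "y", "z"))
            if xs is None or ys is None or zs is None:
                continue
            rs = _attr_ci(node, "radius")
            if rs is None:
                report.skip(f"{tag} {counters[tag]}: node missing Radius")
                continue
            try:
                atom = PseudoAtom((float(xs), float(ys), float(zs)), float(rs))
            except ValueError as exc:
                report.skip(f"{tag} {counters[tag]}: {exc}")
                continue
            atoms.append(atom)
            report.records_read += 1
        if atoms:
            cavities.append(
                Cavity(id=f"{tag}{counters[tag]}", type=cav_type, atoms=atoms)
            )
    if counters["tunnel"] + counters["pore"] == 0:
        raise ValueError("no tunnel or pore elements found")
    return CavitySet(protein_id=protein_id, source=source, cavities=cavities), report


# ---------------------------------------------------------------------------
# embedded cleft records (script files with numbered clusters)
# ---------------------------------------------------------------------------

_CLUSTER_RE = re.compile(r"cluster\s*(?:no\.?\s*)?(\d+)", re.IGNORECASE)
_VOLUME_RE = re.compile(r"volume\D{0,16}?(\d+(?:\.\d+)?)", re.IGNORECASE)
_DEFAULT_RECORD_RE = re.compile(r"\b(ATOM|HETATM)\b")


def read_embedded_cleft_records(
    stream: Union[IO[str], str],
    protein_id: str,
    source: str = "clefts",
    default_radius: float = 1.4,
    record_pattern: re.Pattern[str] = _DEFAULT_RECORD_RE,
) -> tuple[CavitySet, ParseReport]:
    """Read CLEFT cavities embedded in a script-like text file.

    Dummy-atom lines (matched by ``record_pattern``) are grouped into
    numbered clusters: a line mentioning "cluster N" starts cluster N, and
    a "volume <value>" annotation at or after the cluster marker becomes
    that cluster's volume.  Records before any marker form an implicit
    first cluster.  Cluster order follows the file — clefts are typically
    listed in decreasing volume order and are never re-sorted here.
    Records without a radius field get ``default_radius``.
    """
    text = stream if isinstance(stream, str) else stream.read()
    report = ParseReport()
    clusters: list[dict] = []
    current: Optional[dict] = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        mcl = _CLUSTER_RE.search(line)
        if mcl and not record_pattern.search(line):
            current = {"volume": None, "atoms": []}
            clusters.append(current)
            mvol = _VOLUME_RE.search(line)
            if mvol:
                current["volume"] = float(mvol.group(1))
            continue
        mvol = _VOLUME_RE.search(line)
        if mvol and not record_pattern.search(line):
            if current is None:
                current = {"volume": None, "atoms": []}
                clusters.append(current)
            current["volume"] = float(mvol.group(1))
            continue
        if record_pattern.search(line):
            rec = _parse_pdb_like_line(line[line.index(record_pattern.search(line).group(1)):])
            if rec is None:
                report.skip(f"line {lineno}: unparseable dummy-atom record")
                continue
            serial, _resnum, x, y, z, extra = rec
            radius = next((v for v in extra if v > 0), default_radius)
            if current is None:
                current = {"volume": None, "atoms": []}
                clusters.append(current)
            current["atoms"].append(PseudoAtom((x, y, z), radius, serial=serial))
            report.records_read += 1

    clusters = [c for c in clusters if c["atoms"]]
    if not clusters:
        raise ValueError("no clusters with dummy-atom records recognized")
    cavities = [
        Cavity(
            id=f"cleft{k + 1}",
            type=CavityType.CLEFT,
            atoms=c["atoms"],
            volume=c["volume"],
        )
        for k, c in enumerate(clusters)
    ]
    return CavitySet(protein_id=protein_id, source=source, cavities=cavities), report


# ---------------------------------------------------------------------------
# merging and CSV reports
# ---------------------------------------------------------------------------

def merge_cavity_sets(sets: Sequence[CavitySet]) -> CavitySet:
    """Fuse per-type cavity sets of one protein (e.g. clefts + tunnels +
    pores) into one set, concatenating cavities in input order.  Colliding
    cavity ids are disambiguated by prefixing the source name."""
    if not sets:
        raise ValueError("nothing to merge")
    pid = sets[0].protein_id
    for s in sets[1:]:
        if s.protein_id != pid:
            raise ValueError(f"protein mismatch: {pid!r} vs {s.protein_id!r}")
    seen: set[str] = set()
    cavities: list[Cavity] = []
    for s in sets:
        for cav in s:
            cid = cav.id
            if cid in seen:
                cid = f"{s.source}:{cav.id}"
                k = 2
                while cid in seen:
                    cid = f"{s.source}:{cav.id}#{k}"
                    k += 1
            seen.add(cid)
            cavities.append(
                Cavity(id=cid, type=cav.type, atoms=cav.atoms, volume=cav.volume)
            )
    source = "+".join(dict.fromkeys(s.source for s in sets))
    return CavitySet(protein_id=pid, source=source, cavities=cavities)


def write_counts_csv(
    rows: Iterable[tuple[str, str, bool, ClassificationCounts]],
    stream: IO[str],
) -> None:
    """Counts CSV: protein_id, method, repetitions_removed, tp, fp, fn, tn
    (empty when unset)."""
    w = csv.writer(stream, lineterminator="\n")
    w.writerow(["protein_id", "method", "repetitions_removed", "tp", "fp", "fn", "tn"])
    for pid, method, removed, c in rows:
        w.writerow(
            [pid, method, str(removed).lower(), c.tp, c.fp, c.fn,
             "" if c.tn is None else c.tn]
        )
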