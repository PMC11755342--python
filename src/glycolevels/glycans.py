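"""Glycan compositions, Oxford-style nomenclature, and mass bookkeeping.

N-glycans observed on IgG-type antibodies are compositions of five residue
kinds: hexose (Hex: mannose, galactose, glucose — mass-indistinguishable),
N-acetylhexosamine (HexNAc), deoxyhexose (dHex, core fucose), and the two
sialic acids Neu5Ac and Neu5Gc.  Mass spectrometry sees only the composition,
so every name is reduced to a residue-count vector; linkage and arm
decorations (``[3]``/``[6]``, ``(2,6)``) are retained as isomer metadata but
do not contribute to identity at the MS level.

Residue masses are derived from elemental formulas (single source of truth),
so the familiar nominal masses — Hex 162, dHex 146, Neu5Ac 291 — fall out of
the isotope tables rather than being hard-coded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml
from pyteomics import mass as _pmass

__all__ = [
    "RESIDUES",
    "RESIDUE_FORMULAS",
    "OXFORD_ALIASES",
    "GlycanParseError",
    "GlycanComposition",
    "Backbone",
    "GlycoSpecies",
    "residue_mass",
    "parse_oxford_name",
    "composition_mass",
    "peptide_mass",
    "species_mass",
    "isobaric_groups",
    "read_glycan_library",
    "read_backbone_yaml",
]

PROTON_MASS = 1.007276  # Da, mass of H+

RESIDUES = ("Hex", "HexNAc", "dHex", "Neu5Ac", "Neu5Gc")

#: Elemental formulas of glycan *residues* (monosaccharide minus water, i.e.
#: the mass added upon glycosidic bond formation).
RESIDUE_FORMULAS = {
    "Hex": "C6H10O5",
    "HexNAc": "C8H13NO5",
    "dHex": "C6H10O4",
    "Neu5Ac": "C11H17NO8",
    "Neu5Gc": "C11H17NO9",
}

# integer masses of the most abundant isotopes, for nominal-mass bookkeeping
_NOMINAL_ATOM = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for elem, n in _FORMULA_TOKEN.findall(formula):
        if elem:
            out[elem] = out.get(elem, 0) + (int(n) if n else 1)
    return out


def residue_mass(kind: str, mode: str = "mono") -> float:
    """Mass of one glycan residue in the given mode (mono, avg, nominal)."""
    formula = RESIDUE_FORMULAS[kind]
    if mode == "mono":
        return _pmass.calculate_mass(formula=formula)
    if mode == "avg":
        return _pmass.calculate_mass(formula=formula, average=True)
    if mode == "nominal":
        return float(
            sum(_NOMINAL_ATOM[e] * n for e, n in _parse_formula(formula).items())
        )
    raise ValueError(f"unknown mass mode {mode!r}")


def residue_formula(kind: str) -> dict[str, int]:
    return _parse_formula(RESIDUE_FORMULAS[kind])


class GlycanParseError(ValueError):
    """Raised when a glycan name cannot be interpreted."""


@dataclass(frozen=True)
class GlycanComposition:
    """A residue-count vector with its canonical Oxford-style name.

    ``isomer_label`` holds arm/linkage decorations stripped during parsing
    (e.g. ``"[6]"`` or ``"(2,6)[3]"``); compositions differing only in the
    label compare equal in counts and collapse to one canonical name.
    """

    counts: tuple[int, int, int, int, int]  # ordered as RESIDUES
    canonical_name: str
    isomer_label: str = ""
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.counts) != len(RESIDUES):
            raise ValueError("counts must have one entry per residue kind")
        if any(c < 0 for c in self.counts):
            raise ValueError("residue counts must be non-negative")

    @classmethod
    def from_dict(
        cls, counts: dict[str, int], name: str | None = None, **kw
    ) -> "GlycanComposition":
        vec = tuple(int(counts.get(r, 0)) for r in RESIDUES)
        return cls(vec, name if name is not None else _canonical_name(vec), **kw)

    def as_dict(self) -> dict[str, int]:
        return {r: c for r, c in zip(RESIDUES, self.counts) if c}

    def __getitem__(self, kind: str) -> int:
        return self.counts[RESIDUES.index(kind)]

    @property
    def total_residues(self) -> int:
        return sum(self.counts)

    def add(self, kind: str, n: int = 1) -> "GlycanComposition":
        """Composition with ``n`` extra residues of ``kind`` (n may be < 0)."""
        i = RESIDUES.index(kind)
        vec = list(self.counts)
        vec[i] += n
        if vec[i] < 0:
            raise ValueError("residue count would become negative")
        tvec = tuple(vec)
        return GlycanComposition(tvec, _canonical_name(tvec))

    def mass(self, mode: str = "mono") -> float:
        return composition_mass(self, mode)

    def elemental_formula(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for kind, n in zip(RESIDUES, self.counts):
            for e, k in residue_formula(kind).items():
                out[e] = out.get(e, 0) + k * n
        return out


def _canonical_name(vec: tuple[int, ...]) -> str:
    hex_, hexnac, dhex, neu5ac, neu5gc = vec
    if not any(vec):
        return "none"
    if hexnac == 2 and dhex == 0 and neu5ac == 0 and neu5gc == 0 and hex_ >= 1:
        return f"M{hex_}"
    if hexnac >= 2 and hex_ >= 3 and dhex <= 1:
        name = ("F" if dhex else "") + f"A{hexnac - 2}G{hex_ - 3}"
        if neu5ac:
            name += f"S{neu5ac}"
        if neu5gc:
            name += f"Sg{neu5gc}"
        return name
    # not expressible in the compact grammar: fall back to explicit counts
    return "".join(f"{r}{c}" for r, c in zip(RESIDUES, vec) if c)


#: Hybrid-type and otherwise irregular names used for mAb glycans whose
#: residue arithmetic the compact grammar does not define.  Compositions
#: follow the usual reading of hybrid names (Man5 core plus one processed
#: GlcNAc antenna); they are an explicit, auditable assumption.
OXFORD_ALIASES: dict[str, dict[str, int]] = {
    "A1G0-M5": {"HexNAc": 3, "Hex": 5},
    "A1G1-M5": {"HexNAc": 3, "Hex": 6},
    "FA1G0-M5": {"HexNAc": 3, "Hex": 5, "dHex": 1},
    "FA1G1-M5": {"HexNAc": 3, "Hex": 6, "dHex": 1},
    "A1G1Sg1-M5": {"HexNAc": 3, "Hex": 6, "Neu5Gc": 1},
    "M3-F": {"HexNAc": 2, "Hex": 3, "dHex": 1},
    # "-U" marks a structure distinguished by released-glycan analysis; it is
    # kept as a distinct species identity (it is listed separately from M6).
    "M6-U": {"HexNAc": 2, "Hex": 6},
}

_ALIAS_LOOKUP = {k.lower(): k for k in OXFORD_ALIASES}

# decorations: arm labels [3]/[6] and linkage labels (2,3)/(2,6)
_DECORATION = re.compile(r"\[\d\]|\(\d,\d\)")

_GRAMMAR = re.compile(
    r"""^
    (?P<fuc>F)?
    (?:
        M(?P<man>\d+)
      | A(?P<ant>\d+) G(?P<gal>\d+) (?:aG(?P<agal>\d+))?
    )
    (?:S(?P<neu5ac>\d+))?
    (?:Sg(?P<neu5gc>\d+))?
    $""",
    re.VERBOSE,
)


def parse_oxford_name(
    name: str, aliases: dict[str, dict[str, int]] | None = None
) -> GlycanComposition:
    """Parse an Oxford-style glycan name into a residue composition.

    Grammar: optional leading ``F`` (core fucose); ``A<k>`` antennae give
    HexNAc = 2+k; ``G<k>`` galactoses give Hex = 3+k (``aG<k>`` alpha-Gal
    units add further hexoses); ``S<k>``/``Sg<k>`` give Neu5Ac/Neu5Gc;
    oligomannose ``M<k>`` gives Hex = k on the HexNAc2 core.  Arm and
    linkage decorations are stripped into ``isomer_label``.  Hybrid names
    are resolved through the alias table (:data:`OXFORD_ALIASES` unless a
    user table is supplied, which takes precedence).
    """
    raw = name.strip()
    if not raw:
        raise GlycanParseError("empty glycan name")

    decorations = "".join(_DECORATION.findall(raw))
    stripped = _DECORATION.sub("", raw).strip()

    if stripped.lower() in ("none", ""):
        if stripped.lower() == "none":
            return GlycanComposition((0,) * 5, "none", isomer_label=decorations)
        raise GlycanParseError(f"glycan name {raw!r} is only decorations")

    tables = []
    if aliases:
        tables.append({k.lower(): (k, v) for k, v in aliases.items()})
    tables.append({k.lower(): (k, OXFORD_ALIASES[k]) for k in OXFORD_ALIASES})
    for table in tables:
        hit = table.get(stripped.lower())
        if hit is not None:
            canon, counts = hit
            vec = tuple(int(counts.get(r, 0)) for r in RESIDUES)
            return GlycanComposition(
                vec, canon, isomer_label=decorations, aliases=(raw,) if raw != canon else ()
            )

    m = _GRAMMAR.match(stripped)
    if m is None:
        bad = stripped.split("-")[0] if "-" in stripped else stripped
        raise GlycanParseError(
            f"cannot parse glycan name {raw!r}: unrecognised token {bad!r} "
            "(add it to the alias table if it is a hybrid or irregular name)"
        )
    counts = {r: 0 for r in RESIDUES}
    if m.group("fuc"):
        counts["dHex"] = 1
    if m.group("man") is not None:
        counts["HexNAc"] = 2
        counts["Hex"] = int(m.group("man"))
    else:
        counts["HexNAc"] = 2 + int(m.group("ant"))
        counts["Hex"] = 3 + int(m.group("gal")) + int(m.group("agal") or 0)
    counts["Neu5Ac"] = int(m.group("neu5ac") or 0)
    counts["Neu5Gc"] = int(m.group("neu5gc") or 0)
    vec = tuple(counts[r] for r in RESIDUES)
    canon = _canonical_name(vec)
    return GlycanComposition(
        vec, canon, isomer_label=decorations, aliases=(raw,) if raw != canon else ()
    )


def composition_mass(c: GlycanComposition, mode: str = "mono") -> float:
    """Total residue mass of a composition (mono, avg, or nominal)."""
    return sum(n * residue_mass(kind, mode) for kind, n in zip(RESIDUES, c.counts))


_LEVELS = ("peptide", "fc2", "heavy_chain", "intact")


def peptide_mass(
    sequence: str,
    mode: str = "mono",
    modifications: dict[str, str] | None = None,
) -> float:
    """Neutral mass of a peptide: residue masses plus one water.

    ``modifications`` maps an amino-acid letter to the elemental formula of a
    fixed modification (e.g. ``{"C": "C2H3NO"}`` for carbamidomethyl-Cys),
    added once per occurrence of the letter.
    """
    if mode not in ("mono", "avg"):
        raise ValueError(f"unknown mass mode {mode!r}")
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = set(seq) - set(_pmass.std_aa_mass)
    if bad:
        raise ValueError(f"unknown amino-acid letter(s): {sorted(bad)}")
    average = mode == "avg"
    m = _pmass.calculate_mass(sequence=seq, average=average)
    for letter, formula in (modifications or {}).items():
        n = seq.count(letter.upper())
        if n:
            m += n * _pmass.calculate_mass(formula=formula, average=average)
    return m


@dataclass(frozen=True)
class Backbone:
    """The aglycosylated scaffold carrying 1 or 2 N-glycosylation sites.

    Defined either by an amino-acid ``sequence`` (masses computed) or by
    fixed neutral masses (``mono_mass``/``avg_mass``, at least one).  The
    intact level has two sites (one per heavy chain); all others one.
    """

    identifier: str
    level: str
    sequence: str | None = None
    mono_mass: float | None = None
    avg_mass: float | None = None
    n_sites: int | None = None
    modifications: dict[str, str] | None = field(default=None, hash=False)

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise ValueError(f"level must be one of {_LEVELS}, got {self.level!r}")
        if self.sequence is None and self.mono_mass is None and self.avg_mass is None:
            raise ValueError("backbone needs a sequence or a fixed mass")
        if self.sequence is not None and (
            self.mono_mass is not None or self.avg_mass is not None
        ):
            raise ValueError("give a sequence OR fixed masses, not both")
        expected = 2 if self.level == "intact" else 1
        if self.n_sites is None:
            object.__setattr__(self, "n_sites", expected)
        elif self.n_sites != expected:
            raise ValueError(
                f"level {self.level!r} has {expected} glycosylation site(s)"
            )

    def mass(self, mode: str = "mono") -> float:
        if self.sequence is not None:
            return peptide_mass(self.sequence, mode, self.modifications)
        if mode == "mono":
            if self.mono_mass is None:
                raise ValueError(
                    f"backbone {self.identifier!r} has no monoisotopic mass"
                )
            return self.mono_mass
        if mode == "avg":
            if self.avg_mass is None:
                raise ValueError(f"backbone {self.identifier!r} has no average mass")
            return self.avg_mass
        raise ValueError(f"unknown mass mode {mode!r}")


@dataclass(frozen=True)
class GlycoSpecies:
    """A backbone plus 0..n_sites glycans; an empty glycan list is the
    unoccupied site ("none"), which is a first-class species.  ``label``
    overrides the derived name (used e.g. for isobaric mass groups)."""

    backbone: Backbone
    glycans: tuple[GlycanComposition, ...] = ()
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.glycans) > self.backbone.n_sites:
            raise ValueError(
                f"{len(self.glycans)} glycans on a backbone with "
                f"{self.backbone.n_sites} site(s)"
            )
        # sites are interchangeable: store in canonical (sorted) order
        ordered = tuple(
            sorted(self.glycans, key=lambda g: (g.counts, g.canonical_name))
        )
        object.__setattr__(self, "glycans", ordered)

    @property
    def name(self) -> str:
        if self.label is not None:
            return self.label
        if not self.glycans:
            pads = ["none"] * self.backbone.n_sites
        else:
            pads = [g.canonical_name for g in self.glycans]
            pads += ["none"] * (self.backbone.n_sites - len(self.glycans))
        return "/".join(pads) if self.backbone.n_sites > 1 else pads[0]

    def total_glycan_counts(self) -> tuple[int, ...]:
        vec = [0] * len(RESIDUES)
        for g in self.glycans:
            for i, c in enumerate(g.counts):
                vec[i] += c
        return tuple(vec)

    def mass(self, mode: str = "mono") -> float:
        return species_mass(self, mode)


def species_mass(s: GlycoSpecies, mode: str = "mono") -> float:
    """Neutral mass of a glyco-species: backbone plus summed residue masses
    (additive; the residue-mass convention already accounts for water)."""
    return s.backbone.mass(mode) + sum(
        composition_mass(g, mode) for g in s.glycans
    )


def isobaric_groups(
    library: list[GlycoSpecies], tol: float, mode: str = "avg"
) -> list[list[GlycoSpecies]]:
    """Partition species into isobaric groups at mass tolerance ``tol``.

    Single-linkage: species whose masses chain together with consecutive
    gaps <= tol end up in one group (transitive closure on the line).
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if not library:
        return []
    order = sorted(library, key=lambda s: species_mass(s, mode))
    groups = [[order[0]]]
    last = species_mass(order[0], mode)
    for s in order[1:]:
        m = species_mass(s, mode)
        if m - last <= tol:
            groups[-1].append(s)
        else:
            groups.append([s])
        last = m
    return groups


# ---------------------------------------------------------------------------
# external interfaces

def read_glycan_library(path) -> pd.DataFrame:
    """Read a glycan library CSV.

    Columns: ``name`` plus optional explicit counts (Hex, HexNAc, dHex,
    Neu5Ac, Neu5Gc), optional ``rel_abundance`` and ``level``.  Rows without
    explicit counts are parsed from the name.  Returns a DataFrame indexed by
    canonical name with count columns, a ``composition`` object column, and
    whatever metadata columns were present.
    """
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise ValueError("glycan library CSV needs a 'name' column")
    comps = []
    for _, row in df.iterrows():
        if all(r in df.columns and pd.notna(row[r]) for r in RESIDUES):
            comps.append(
                GlycanComposition.from_dict(
                    {r: int(row[r]) for r in RESIDUES}, name=str(row["name"])
                )
            )
        else:
            comps.append(parse_oxford_name(str(row["name"])))
    out = pd.DataFrame(
        {
            "name": [c.canonical_name for c in comps],
            **{r: [c[r] for c in comps] for r in RESIDUES},
            "composition": comps,
        }
    )
    for extra in ("rel_abundance", "level"):
        if extra in df.columns:
            out[extra] = df[extra].to_numpy()
    return out.set_index("name")


def read_backbone_yaml(path) -> Backbone:
    """Read a backbone definition from YAML (sequence or fixed masses)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return Backbone(
        identifier=cfg.get("identifier", "backbone"),
        level=cfg["level"],
        sequence=cfg.get("sequence"),
        mono_mass=cfg.get("mono_mass"),
        avg_mass=cfg.get("avg_mass"),
        n_sites=cfg.get("n_sites"),
        modifications=cfg.get("modifications"),
    )
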