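"""Fatty-acid label parsing and chemotaxonomic classification.

Bacterial fatty acids are reported in a compact chromatography dialect:
``a-C15:0`` (anteiso-pentadecanoic), ``i-C13:0`` (iso-tridecanoic),
``C18:1n7c`` (cis-vaccenic, one double bond at the omega-7 position),
``2OH-C14:0`` (2-hydroxy-myristic), ``cyclo-C17:0`` (cyclopropane ring).
This module parses that dialect into a structural descriptor and assigns
each acid to the disjoint chemotaxonomic classes used for Gram-group and
genus comparisons: chain-length classes (SCFA/MCFA/LCFA/VLCFA), structural
classes (PUFA, n-SFA, br-SFA, n-MUFA, hydroxy-FA, cyclic-FA), geometric
isomerism (cis/trans) and branching type (iso/anteiso).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "FattyAcidDescriptor",
    "FAClassSummary",
    "FAParseError",
    "parse_fa_label",
    "canonical_label",
    "chain_length_class",
    "structural_class",
    "summarize_profile",
    "STRUCTURAL_CLASSES",
    "CHAIN_CLASSES",
]

STRUCTURAL_CLASSES = (
    "cyclic_FA",
    "hydroxy_FA",
    "PUFA",
    "n_MUFA",
    "br_SFA",
    "n_SFA",
    "br_UFA_unknown",
)
CHAIN_CLASSES = ("SCFA", "MCFA", "LCFA", "VLCFA", "out_of_range")

_BRANCHES = ("none", "iso", "anteiso", "other")
_GEOMETRIES = ("cis", "trans", "unspecified")


class FAParseError(ValueError):
    """A fatty-acid label that does not match the supported grammar."""


@dataclass(frozen=True)
class FattyAcidDescriptor:
    """Structural representation of one fatty acid.

    ``carbons`` counts acyl-chain carbons, ``double_bonds`` the number of
    C=C bonds, ``branch`` the methyl-branch type (iso = omega-2 carbon,
    anteiso = omega-3 carbon), ``geometry`` the double-bond configuration,
    ``db_position`` the positional token ("n7" for omega notation, a bare
    digit string for delta notation), ``hydroxyl_positions`` the carbons
    bearing OH groups and ``cyclic`` whether the chain carries a ring.
    """

    raw_label: str
    carbons: int
    double_bonds: int = 0
    branch: str = "none"
    geometry: str = "unspecified"
    db_position: str | None = None
    hydroxyl_positions: tuple[int, ...] = ()
    cyclic: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"carbons must be >= 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if not self.double_bonds < self.carbons / 2 + 1:
            raise ValueError(
                f"{self.double_bonds} double bonds impossible for "
                f"{self.carbons} carbons"
            )
        if self.branch not in _BRANCHES:
            raise ValueError(f"unknown branch type {self.branch!r}")
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.branch == "anteiso" and self.carbons < 5:
            raise ValueError("anteiso branching requires >= 5 carbons")
        if self.geometry in ("cis", "trans") and self.double_bonds < 1:
            raise ValueError("cis/trans geometry requires >= 1 double bond")


_HYPHENS = str.maketrans({"‐": "-", "–": "-", "—": "-"})

_PREFIX_PATTERNS = [
    (re.compile(r"^(anteiso)-", re.I), "anteiso"),
    (re.compile(r"^(iso)-", re.I), "iso"),
    (re.compile(r"^(cyclo|cy)-", re.I), "cyclic"),
    (re.compile(r"^a(?:-|(?=C\d))", re.I), "anteiso"),
    (re.compile(r"^i(?:-|(?=C\d))", re.I), "iso"),
    (re.compile(r"^(\d+(?:,\d+)*)OH-", re.I), "hydroxy"),
]
_CORE_RE = re.compile(r"^C(\d{1,2}):(\d{1,2})", re.I)
_SUFFIX_N = re.compile(r"^n(\d+)(c|t)?$", re.I)
_SUFFIX_CISTRANS = re.compile(r"^(cis|trans)(\d+)$", re.I)
_SUFFIX_CT = re.compile(r"^(c|t)$", re.I)


def parse_fa_label(label: str) -> FattyAcidDescriptor:
    """Parse one fatty-acid label into a :class:`FattyAcidDescriptor`.

    The grammar is the union of dialects seen in bacterial FAME tables:
    optional prefixes ``a-``/``anteiso-``, ``i-``/``iso-``, ``cyclo-``,
    ``<pos>OH-``; core ``C<carbons>:<double_bonds>``; optional suffix
    ``n<k>`` (omega position) with optional ``c``/``t``, ``cis<k>``/
    ``trans<k>`` (delta position), or bare ``c``/``t``. Prefix matching is
    case-insensitive and tolerant of a missing hyphen (``aC15:0``).

    Raises :class:`FAParseError` naming the offending token; never
    silently defaults.
    """
    if not label or not label.strip():
        raise FAParseError("empty fatty-acid label")
    text = label.strip().translate(_HYPHENS)
    rest = text
    branch = "none"
    cyclic = False
    hydroxyls: tuple[int, ...] = ()

    progressed = True
    while progressed:
        progressed = False
        for pattern, kind in _PREFIX_PATTERNS:
            m = pattern.match(rest)
            if not m:
                continue
            if kind in ("anteiso", "iso"):
                if branch != "none":
                    raise FAParseError(
                        f"conflicting branch prefixes in {label!r}"
                    )
                branch = kind
            elif kind == "cyclic":
                cyclic = True
            else:
                hydroxyls = tuple(
                    sorted(int(p) for p in m.group(1).split(","))
                )
            rest = rest[m.end():]
            progressed = True
            break

    core = _CORE_RE.match(rest)
    if not core:
        raise FAParseError(
            f"label {label!r}: expected C<carbons>:<double_bonds>, "
            f"got {rest!r}"
        )
    carbons = int(core.group(1))
    double_bonds = int(core.group(2))
    suffix = rest[core.end():]

    geometry = "unspecified"
    db_position: str | None = None
    if suffix:
        if m := _SUFFIX_N.match(suffix):
            db_position = f"n{int(m.group(1))}"
            if m.group(2):
                geometry = "cis" if m.group(2).lower() == "c" else "trans"
        elif m := _SUFFIX_CISTRANS.match(suffix):
            geometry = m.group(1).lower()
            db_position = str(int(m.group(2)))
        elif m := _SUFFIX_CT.match(suffix):
            geometry = "cis" if m.group(1).lower() == "c" else "trans"
        else:
            raise FAParseError(
                f"label {label!r}: unrecognized suffix {suffix!r}"
            )

    try:
        return FattyAcidDescriptor(
            raw_label=text,
            carbons=carbons,
            double_bonds=double_bonds,
            branch=branch,
            geometry=geometry,
            db_position=db_position,
            hydroxyl_positions=hydroxyls,
            cyclic=cyclic,
        )
    except ValueError as exc:
        raise FAParseError(f"label {label!r}: {exc}") from exc


def canonical_label(d: FattyAcidDescriptor) -> str:
    """Render a descriptor in the canonical dialect.

    ``parse_fa_label(canonical_label(d))`` reproduces ``d`` (modulo
    ``raw_label``).
    """
    parts: list[str] = []
    if d.hydroxyl_positions:
        parts.append(",".join(str(p) for p in d.hydroxyl_positions) + "OH-")
    if d.cyclic:
        parts.append("cyclo-")
    if d.branch == "anteiso":
        parts.append("a-")
    elif d.branch == "iso":
        parts.append("i-")
    parts.append(f"C{d.carbons}:{d.double_bonds}")
    geo = {"cis": "c", "trans": "t"}.get(d.geometry, "")
    if d.db_position is not None:
        if d.db_position.startswith("n"):
            parts.append(d.db_position + geo)
        else:
            # delta notation only exists with explicit geometry
            parts.append(d.geometry + d.db_position)
    elif geo:
        parts.append(geo)
    return "".join(parts)


def chain_length_class(
    d: FattyAcidDescriptor, c6_class: str = "MCFA"
) -> str:
    """Chain-length class from the carbon count.

    SCFA below 6 carbons, MCFA 7-12, LCFA 13-21, VLCFA 22-24, longer
    chains ``out_of_range``. The 6-carbon count sits between the stated
    SCFA and MCFA bounds; it is assigned to ``c6_class`` (default MCFA,
    keeping the classes contiguous).
    """
    c = d.carbons
    if c < 6:
        return "SCFA"
    if c == 6:
        if c6_class not in ("SCFA", "MCFA"):
            raise ValueError("c6_class must be 'SCFA' or 'MCFA'")
        return c6_class
    if c <= 12:
        return "MCFA"
    if c <= 21:
        return "LCFA"
    if c <= 24:
        return "VLCFA"
    return "out_of_range"


def structural_class(d: FattyAcidDescriptor) -> str:
    """Assign exactly one structural class.

    The reported class sums are disjoint, so multi-feature acids are
    resolved by a total precedence order: cyclic > hydroxy > PUFA >
    n-MUFA > br-SFA > n-SFA; a branched *and* unsaturated acid (not
    covered by the named groups) falls through to ``br_UFA_unknown``.
    """
    if d.cyclic:
        return "cyclic_FA"
    if d.hydroxyl_positions:
        return "hydroxy_FA"
    if d.double_bonds >= 2:
        return "PUFA"
    if d.double_bonds == 1 and d.branch == "none":
        return "n_MUFA"
    if d.double_bonds == 0 and d.branch != "none":
        return "br_SFA"
    if d.double_bonds == 0:
        return "n_SFA"
    return "br_UFA_unknown"


@dataclass
class FAClassSummary:
    """Per-sample class sums as percent of total fatty-acid weight.

    Structural-class sums plus ``unknown_FAs`` (labels the parser cannot
    interpret, and branched-unsaturated acids outside the named groups)
    plus ``minor_FA_pool`` close to 100 %. Chain-length, geometry and
    branching sums are computed over the classified (non-minor, parseable)
    acids only, so each is bounded by 100 %.
    """

    sample_id: str = ""
    PUFAs: float = 0.0
    n_SFAs: float = 0.0
    br_SFAs: float = 0.0
    n_MUFAs: float = 0.0
    hydroxy_FAs: float = 0.0
    cyclic_FAs: float = 0.0
    unknown_FAs: float = 0.0
    SCFAs: float = 0.0
    MCFAs: float = 0.0
    LCFAs: float = 0.0
    VLCFAs: float = 0.0
    cis_FAs: float = 0.0
    trans_FAs: float = 0.0
    iso_FAs: float = 0.0
    anteiso_FAs: float = 0.0
    minor_FA_pool: float = 0.0

    _STRUCTURAL_FIELDS = (
        "PUFAs", "n_SFAs", "br_SFAs", "n_MUFAs",
        "hydroxy_FAs", "cyclic_FAs", "unknown_FAs",
    )

    def structural_total(self) -> float:
        return sum(getattr(self, f) for f in self._STRUCTURAL_FIELDS)

    def as_dict(self) -> dict[str, float | str]:
        out: dict[str, float | str] = {"sample_id": self.sample_id}
        for name in self.__dataclass_fields__:
            if name != "sample_id":
                out[name] = getattr(self, name)
        return out


_CLASS_TO_FIELD = {
    "PUFA": "PUFAs",
    "n_SFA": "n_SFAs",
    "br_SFA": "br_SFAs",
    "n_MUFA": "n_MUFAs",
    "hydroxy_FA": "hydroxy_FAs",
    "cyclic_FA": "cyclic_FAs",
    "br_UFA_unknown": "unknown_FAs",
}
_CHAIN_TO_FIELD = {
    "SCFA": "SCFAs", "MCFA": "MCFAs", "LCFA": "LCFAs", "VLCFA": "VLCFAs",
}


def summarize_profile(
    weights: Mapping[str, float],
    minor_threshold_pct: float = 1.0,
    sample_id: str = "",
    c6_class: str = "MCFA",
) -> FAClassSummary:
    """Summarize a per-sample fatty-acid weight profile into class sums.

    ``weights`` maps fatty-acid labels to nonnegative weights (any common
    unit; the output is relative). Acids whose relative abundance is at or
    below ``minor_threshold_pct`` (default 1 %, i.e. only acids with
    content *higher than* 1 % are classified) are pooled into
    ``minor_FA_pool`` and excluded from every class sum. Labels failing
    the parser count under ``unknown_FAs`` rather than being dropped, so
    the structural sums close to 100 %.
    """
    if any(w < 0 for w in weights.values()):
        raise ValueError("fatty-acid weights must be nonnegative")
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("all-zero fatty-acid profile cannot be summarized")

    summary = FAClassSummary(sample_id=sample_id)
    for label, w in weights.items():
        pct = 100.0 * float(w) / total
        if pct <= minor_threshold_pct:
            summary.minor_FA_pool += pct
            continue
        try:
            d = parse_fa_label(label)
        except FAParseError:
            summary.unknown_FAs += pct
            continue
        cls = structural_class(d)
        setattr(summary, _CLASS_TO_FIELD[cls],
                getattr(summary, _CLASS_TO_FIELD[cls]) + pct)
        chain = chain_length_class(d, c6_class=c6_class)
        if chain in _CHAIN_TO_FIELD:
            setattr(summary, _CHAIN_TO_FIELD[chain],
                    getattr(summary, _CHAIN_TO_FIELD[chain]) + pct)
        if d.geometry == "cis":
            summary.cis_FAs += pct
        elif d.geometry == "trans":
            summary.trans_FAs += pct
        if d.branch == "iso":
            summary.iso_FAs += pct
        elif d.branch == "anteiso":
            summary.anteiso_FAs += pct
    return summary
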