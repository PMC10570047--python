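"""DNA template descriptors for the single-molecule R-loop assay.

A template is a linear, surface-immobilized transcription construct: a
promoter upstream of the start site +1, a stall site where the elongation
complex halts before NTP injection, and a downstream end that mimics a DNA
double-strand break (blunt, or with a 3'/5' single-stranded overhang).
Coordinates are 1-based template positions with +1 the transcription start
and upstream positions negative.

Presets DT1..DT8 encode the constructs of the study this package models:

* DT1 - 20-nt 3'-overhang at +81..+101, Cy5 on the nontemplate strand at +8,
  Cy3 on the RNA 5'-end (labeling scheme III), biotin at -58.
* DT2 - as DT1 but with a 20-nt 5'-overhang.
* DT3 - blunt downstream end at +101.
* DT4 - DT3 with the G-quadruplex-forming sequence (+13..+27) deleted.
* DT5 - DT3 with an inserted T-less cassette (stalls past it without UTP).
* DT6 - DT3 with biotin moved to the downstream end (streptavidin roadblock).
* DT7 - 5-nt 3'-overhang variant.
* DT8 - 1.1-kb template ending at +1103, Cy5 at the downstream end; the RNAP
  arrival is read out by Cy5 PIFE instead of FRET.

Label-scheme variants of DT3 used to localize the R-loop border:
``DT3-I`` (both dyes at the downstream end, opposite strands), ``DT3-II``
(both dyes on the nontemplate strand at +54/+33), ``DT3-III`` (= DT3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "DyeLabel",
    "TemplateSpec",
    "build_template",
    "list_presets",
    "overhang_series",
]

_END_STRUCTURES = ("overhang3", "overhang5", "blunt")
_SCHEMES = ("I", "II", "III", "end")
_DYES = ("Cy3", "Cy5")
_STRANDS = ("template", "nontemplate", "RNA")


@dataclass(frozen=True)
class DyeLabel:
    """One fluorophore on the construct."""

    dye: str
    strand: str
    position: int

    def __post_init__(self) -> None:
        if self.dye not in _DYES:
            raise ValueError(f"unknown dye {self.dye!r}; expected one of {_DYES}")
        if self.strand not in _STRANDS:
            raise ValueError(
                f"unknown strand {self.strand!r}; expected one of {_STRANDS}"
            )


@dataclass(frozen=True)
class TemplateSpec:
    """Geometric/chemical description of one linear transcription template."""

    name: str
    upstream_end: int
    downstream_end: int
    stall_site: int
    promoter_window: tuple[int, int]
    end_structure: str
    overhang_len: int
    dye_labels: tuple[DyeLabel, ...]
    biotin_end: str = "upstream"
    scheme: str = "III"
    efficiency_modifiers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.end_structure not in _END_STRUCTURES:
            raise ValueError(
                f"end_structure must be one of {_END_STRUCTURES}, "
                f"got {self.end_structure!r}"
            )
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}, got {self.scheme!r}")
        if self.biotin_end not in ("upstream", "downstream"):
            raise ValueError("biotin_end must be 'upstream' or 'downstream'")
        if self.overhang_len < 0:
            raise ValueError("overhang_len must be >= 0")
        if (self.overhang_len == 0) != (self.end_structure == "blunt"):
            raise ValueError("overhang_len must be 0 iff end_structure is 'blunt'")
        if not self.stall_site < self.downstream_end:
            raise ValueError("stall_site must lie upstream of downstream_end")
        if not self.upstream_end < self.stall_site:
            raise ValueError("upstream_end must lie upstream of stall_site")
        for lab in self.dye_labels:
            if not self.upstream_end <= lab.position <= self.downstream_end:
                raise ValueError(
                    f"dye at {lab.position} outside template "
                    f"[{self.upstream_end}, {self.downstream_end}]"
                )
        n_cy3 = sum(1 for lab in self.dye_labels if lab.dye == "Cy3")
        n_cy5 = sum(1 for lab in self.dye_labels if lab.dye == "Cy5")
        if n_cy3 != 1 or n_cy5 > 1:
            raise ValueError("expect exactly one Cy3 and at most one Cy5 label")

    @property
    def length_bp(self) -> int:
        return self.downstream_end - self.upstream_end + 1

    def dye(self, name: str) -> DyeLabel:
        for lab in self.dye_labels:
            if lab.dye == name:
                return lab
        raise KeyError(f"no {name} label on template {self.name}")


def _short(name, end_structure, overhang_len, labels, scheme="III", **kw):
    return TemplateSpec(
        name=name,
        upstream_end=-58,
        downstream_end=101,
        stall_site=10,
        promoter_window=(-35, -1),
        end_structure=end_structure,
        overhang_len=overhang_len,
        dye_labels=tuple(labels),
        scheme=scheme,
        **kw,
    )


_SCHEME_III_LABELS = (DyeLabel("Cy3", "RNA", 1), DyeLabel("Cy5", "nontemplate", 8))

_PRESETS: dict[str, TemplateSpec] = {
    "DT1": _short("DT1", "overhang3", 20, _SCHEME_III_LABELS),
    "DT2": _short("DT2", "overhang5", 20, _SCHEME_III_LABELS),
    "DT3": _short("DT3", "blunt", 0, _SCHEME_III_LABELS),
    "DT4": _short(
        "DT4", "blunt", 0, _SCHEME_III_LABELS,
        efficiency_modifiers={"g_rich_deleted": 1.0},
    ),
    "DT5": _short(
        "DT5", "blunt", 0, _SCHEME_III_LABELS,
        efficiency_modifiers={"t_less_insert": 1.0},
    ),
    "DT6": _short(
        "DT6", "blunt", 0, _SCHEME_III_LABELS,
        biotin_end="downstream",
        efficiency_modifiers={"streptavidin_roadblock": 1.0},
    ),
    "DT7": _short("DT7", "overhang3", 5, _SCHEME_III_LABELS),
    "DT3-I": _short(
        "DT3-I", "blunt", 0,
        (DyeLabel("Cy3", "nontemplate", 101), DyeLabel("Cy5", "template", 101)),
        scheme="I",
    ),
    "DT3-II": _short(
        "DT3-II", "blunt", 0,
        (DyeLabel("Cy3", "nontemplate", 54), DyeLabel("Cy5", "nontemplate", 33)),
        scheme="II",
    ),
    "DT8": TemplateSpec(
        name="DT8",
        upstream_end=-58,
        downstream_end=1103,
        stall_site=10,
        promoter_window=(-35, -1),
        end_structure="blunt",
        overhang_len=0,
        dye_labels=(DyeLabel("Cy3", "RNA", 1), DyeLabel("Cy5", "nontemplate", 1103)),
        scheme="end",
    ),
}
_PRESETS["DT3-III"] = replace(_PRESETS["DT3"], name="DT3-III")


def list_presets() -> list[str]:
    """Names of the built-in template presets."""
    return sorted(_PRESETS)


def build_template(config: str | dict | TemplateSpec) -> TemplateSpec:
    """Build a validated :class:`TemplateSpec`.

    ``config`` is a preset name (``"DT1"`` .. ``"DT8"``, ``"DT3-I"``,
    ``"DT3-II"``, ``"DT3-III"``), a dict supplying all fields (``dye_labels``
    as ``(dye, strand, position)`` triples), or an already-built spec
    (validated by construction and returned as-is).
    """
    if isinstance(config, TemplateSpec):
        return config
    if isinstance(config, str):
        try:
            return _PRESETS[config]
        except KeyError:
            raise ValueError(
                f"unknown template preset {config!r}; known: {list_presets()}"
            ) from None
    cfg = dict(config)
    labels = tuple(
        lab if isinstance(lab, DyeLabel) else DyeLabel(*lab)
        for lab in cfg.pop("dye_labels")
    )
    if "promoter_window" in cfg:
        cfg["promoter_window"] = tuple(cfg["promoter_window"])
    return TemplateSpec(dye_labels=labels, **cfg)


# Overhang-length series emulating the end-structure dependence experiment:
# R-loop efficiency falls monotonically as the overhang shortens, for both
# polarities, down to the blunt-end basal level. The per-length efficiencies
# are configured values (the study tabulates this dependence graphically).
_OVERHANG_P_RLOOP = {
    "overhang3": [(20, 0.73), (10, 0.55), (5, 0.35), (2, 0.18), (1, 0.12)],
    "overhang5": [(20, 0.60), (10, 0.45), (5, 0.28), (2, 0.15), (1, 0.10)],
}


def overhang_series(polarity: str) -> list[tuple[TemplateSpec, float]]:
    """(template, configured R-loop probability) pairs for one overhang polarity.

    ``polarity`` is ``"overhang3"`` or ``"overhang5"``; lengths run 20 down to
    1 nt.  Used for the overhang-dependence recovery experiment.
    """
    if polarity not in _OVERHANG_P_RLOOP:
        raise ValueError("polarity must be 'overhang3' or 'overhang5'")
    out = []
    for length, p in _OVERHANG_P_RLOOP[polarity]:
        spec = _short(
            f"{'3p' if polarity == 'overhang3' else '5p'}-oh{length}",
            polarity, length, _SCHEME_III_LABELS,
        )
        out.append((spec, p))
    return out
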