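"""Marker-gene definitions for NCLDV screening.

Screening and completeness rest on a set of 20 "ancestral" nucleocytoplasmic
virus orthologous genes (NCVOGs) inferred to have been present in the last
common ancestor of the NCLDV.  The canonical membership of that set is
curated elsewhere; here the ids are configurable labels, with the markers the
pipeline treats specially pinned to their published NCVOG ids: the major
capsid protein (NCVOG0022) and the five core phylogenomic markers — family B
DNA polymerase (NCVOG0038), D5-like helicase-primase (NCVOG0023), genome
packaging ATPase (NCVOG0249), superfamily II helicase (NCVOG0076) and the
VLTF3-like late transcription factor (NCVOG0262).
"""

from __future__ import annotations

from dataclasses import dataclass, field


MCP_ID = "NCVOG0022"

CORE5_IDS = ("NCVOG0038", "NCVOG0023", "NCVOG0249", "NCVOG0076", "NCVOG0262")

# Stand-in labels completing the 20-marker ancestral set; the first six are
# the published ids above, the rest are placeholders a user can override.
DEFAULT_ANCESTRAL_IDS = (
    MCP_ID,
    *CORE5_IDS,
    "NCVOG0211", "NCVOG0236", "NCVOG0271", "NCVOG0274", "NCVOG0276",
    "NCVOG0278", "NCVOG0320", "NCVOG1060", "NCVOG1088", "NCVOG1117",
    "NCVOG1122", "NCVOG1164", "NCVOG1192", "NCVOG1353",
)


@dataclass(frozen=True)
class MarkerDefinition:
    """The ancestral NCVOG marker set used for screening and completeness.

    The MCP is a member of the 20-marker ancestral set but is additionally
    tracked on its own because the selection rule applies it as an
    independent condition ("more than five different hits and/or the MCP").
    """

    marker_ids: tuple[str, ...] = DEFAULT_ANCESTRAL_IDS
    mcp_id: str = MCP_ID
    core5_ids: tuple[str, ...] = CORE5_IDS

    def __post_init__(self) -> None:
        if len(self.marker_ids) != len(set(self.marker_ids)):
            raise ValueError("marker_ids must be unique")
        if len(self.marker_ids) != 20:
            raise ValueError(f"expected 20 ancestral markers, got {len(self.marker_ids)}")
        if len(self.core5_ids) != 5:
            raise ValueError("core5_ids must contain exactly 5 markers")
        if not set(self.core5_ids) <= set(self.marker_ids):
            raise ValueError("core5_ids must be a subset of marker_ids")

    @property
    def ancestral(self) -> frozenset:
        return frozenset(self.marker_ids)

    @property
    def core5(self) -> frozenset:
        return frozenset(self.core5_ids)


DEFAULT_MARKERS = MarkerDefinition()
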