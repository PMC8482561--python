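"""The bibliography-and-databank view: where each piece of data came from.

External databank accessions (ClinVar, KEGG, ...) and literature references
can be attached to any instance element through reified links.  The citrus
schema has no bibliography view at all, so CSCG emulation rejects every
attachment.
"""

from __future__ import annotations

from typing import Optional, Union

from pydantic import BaseModel

from .errors import CapabilityError
from .modes import SchemaMode


class DataBankEntry(BaseModel):
    """An accessioned record in an external database."""

    databank: str
    accession: str
    uri: Optional[str] = None

    def key(self) -> str:
        return f"{self.databank}:{self.accession}"


class BibliographyEntry(BaseModel):
    """A literature reference."""

    id: str
    citation: str
    identifier: Optional[str] = None

    def key(self) -> str:
        return f"bibliography:{self.id}"


Entry = Union[DataBankEntry, BibliographyEntry]


class ReferenceLink(BaseModel):
    """Link from an instance element (by id) to a provenance entry (by key)."""

    element: str
    entry: str


class ProvenanceStore:
    """Holds entries and element->entry links with referential integrity.

    ``element_exists`` is injected by the owning instance so that dangling
    links are rejected at attach time.
    """

    def __init__(self, element_exists, mode: SchemaMode = SchemaMode.CSG) -> None:
        self._element_exists = element_exists
        self.mode = mode
        self.entries: dict[str, Entry] = {}
        self.links: list[ReferenceLink] = []

    def attach_reference(self, element: str, entry: Entry) -> ReferenceLink:
        """Store a link; idempotent for an identical (element, entry) pair."""
        if self.mode is SchemaMode.CSCG:
            raise CapabilityError(
                "the CSCG has no bibliography and databank view; external "
                "references cannot be represented")
        if not self._element_exists(element):
            raise KeyError(f"cannot attach a reference to unknown element {element!r}")
        key = entry.key()
        stored = self.entries.get(key)
        if stored is not None and stored != entry:
            raise ValueError(f"conflicting provenance entries under key {key!r}")
        self.entries[key] = entry
        link = ReferenceLink(element=element, entry=key)
        if link not in self.links:
            self.links.append(link)
        return link

    def references_of(self, element: str) -> list[Entry]:
        return [self.entries[link.entry] for link in self.links
                if link.element == element]

    def drop_element(self, element: str) -> None:
        """Forget every link of a deleted element (referential integrity)."""
        self.links = [link for link in self.links if link.element != element]
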