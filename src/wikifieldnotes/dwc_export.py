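"""Crosswalk occurrence triplets into Darwin Core and write the outputs.

Three artifacts are produced from one in-memory record list (the full
output is a strict superset of the simple one, so the two can never
drift apart):

* a *simple* CSV restricted to standard Darwin Core terms;
* a *full* CSV appending provenance columns (verbatim identification,
  taxon resolution method and scores, consensus class, carried flags) that
  standard Darwin Core cannot express;
* a Darwin Core Archive: a zip of a tab-delimited occurrence core plus a
  ``meta.xml`` mapping every column to its term URI, and a minimal EML stub.

Catalog numbers are per-notebook sequential labels; occurrenceIDs are a
deterministic hash of (notebook, page, annotation offset, name) so
re-extraction of unchanged pages reproduces identical identifiers and
appending new annotations never renumbers existing records.
"""

from __future__ import annotations

import csv
import hashlib
import io
import zipfile
from dataclasses import dataclass, field, fields
from pathlib import Path

from lxml import etree

from .errors import IntegrityError
from .extraction import OccurrenceTriplet
from .referencing import HIGHER_RANKS, ResolutionResult

__all__ = [
    "DarwinCoreRecord",
    "ProvenanceExtension",
    "ArchiveManifest",
    "ExportConfig",
    "crosswalk",
    "assign_identifiers",
    "write_outputs",
    "DWC_TERM_URIS",
]

DWC_NS = "http://rs.tdwg.org/dwc/terms/"
DC_NS = "http://purl.org/dc/terms/"

# One manifest table: record field -> term URI; adding a field is one line.
DWC_TERM_URIS: dict[str, str] = {
    "occurrenceID": DWC_NS + "occurrenceID",
    "catalogNumber": DWC_NS + "catalogNumber",
    "basisOfRecord": DWC_NS + "basisOfRecord",
    "recordedBy": DWC_NS + "recordedBy",
    "eventDate": DWC_NS + "eventDate",
    "verbatimEventDate": DWC_NS + "verbatimEventDate",
    "scientificName": DWC_NS + "scientificName",
    "vernacularName": DWC_NS + "vernacularName",
    "kingdom": DWC_NS + "kingdom",
    "phylum": DWC_NS + "phylum",
    "class_": DWC_NS + "class",
    "order": DWC_NS + "order",
    "family": DWC_NS + "family",
    "genus": DWC_NS + "genus",
    "locality": DWC_NS + "locality",
    "verbatimLocality": DWC_NS + "verbatimLocality",
    "occurrenceRemarks": DWC_NS + "occurrenceRemarks",
    "references": DC_NS + "references",
    "identificationRemarks": DWC_NS + "identificationRemarks",
    "occurrenceStatus": DWC_NS + "occurrenceStatus",
}


@dataclass
class DarwinCoreRecord:
    """One crosswalked occurrence row (``class_`` avoids the keyword)."""

    occurrenceID: str = ""
    catalogNumber: str = ""
    basisOfRecord: str = "HumanObservation"
    recordedBy: str = ""
    eventDate: str = ""
    verbatimEventDate: str = ""
    scientificName: str = ""
    vernacularName: str = ""
    kingdom: str = ""
    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    locality: str = ""
    verbatimLocality: str = ""
    occurrenceRemarks: str = ""
    references: str = ""
    identificationRemarks: str = ""
    occurrenceStatus: str = "present"

    # not exported: hashing inputs kept for identifier assignment
    page_number: int = 0
    char_offset: int = 0

    @classmethod
    def term_fields(cls) -> list[str]:
        return list(DWC_TERM_URIS)

    def row(self) -> list[str]:
        return [str(getattr(self, f)) for f in self.term_fields()]

    @staticmethod
    def header() -> list[str]:
        # external column names use the DwC term, not the Python identifier
        return [uri.rsplit("/", 1)[1] for uri in DWC_TERM_URIS.values()]


@dataclass
class ProvenanceExtension:
    """Per-record provenance that standard Darwin Core cannot carry."""

    verbatimIdentification: str = ""
    taxonResolutionMethod: str = ""
    authorityAIdentifier: str = ""
    authorityBIdentifier: str = ""
    consensusClass: str = ""
    matchScore: str = ""
    dateCarried: str = "false"
    localityCarried: str = "false"

    @classmethod
    def columns(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def row(self) -> list[str]:
        return [getattr(self, f) for f in self.columns()]


@dataclass
class ArchiveManifest:
    """Describes the archive core file layout for meta.xml generation."""

    core_file: str = "occurrence.txt"
    row_type: str = DWC_NS + "Occurrence"
    fields_terminated_by: str = "\\t"
    encoding: str = "UTF-8"
    term_uris: dict[str, str] = field(default_factory=lambda: dict(DWC_TERM_URIS))


@dataclass
class ExportConfig:
    recorded_by: str = "Junius Henderson"
    basis_of_record: str = "HumanObservation"


def crosswalk(
    triplet: OccurrenceTriplet,
    resolution: ResolutionResult | None,
    config: ExportConfig | None = None,
) -> tuple[DarwinCoreRecord, ProvenanceExtension]:
    """Map one triplet (+ its name resolution) onto Darwin Core fields.

    Every triplet yields a record: unresolved names keep the annotator's
    formal name as scientificName with identificationRemarks noting it,
    since unvalidated records are published rather than dropped.
    """
    config = config or ExportConfig()
    rec = DarwinCoreRecord(
        basisOfRecord=config.basis_of_record,
        recordedBy=config.recorded_by,
        occurrenceStatus=triplet.occurrence_status,
        occurrenceRemarks=triplet.entry_excerpt,
        references=triplet.source_permalink,
        page_number=triplet.page_number,
        char_offset=triplet.taxon.char_span[0],
    )
    if triplet.event_date is not None:
        rec.eventDate = triplet.event_date.iso
        rec.verbatimEventDate = triplet.event_date.source_text
    if triplet.locality is not None:
        rec.locality = triplet.locality.formal
        rec.verbatimLocality = triplet.locality.verbatim

    ext = ProvenanceExtension(
        verbatimIdentification=triplet.taxon.formal,
        dateCarried=str(triplet.date_carried).lower(),
        localityCarried=str(triplet.locality_carried).lower(),
    )

    if resolution is not None and resolution.accepted_name is not None:
        rec.scientificName = resolution.accepted_name
        rec.vernacularName = resolution.vernacular_name
        rec.identificationRemarks = resolution.resolution_method
        for rank in HIGHER_RANKS:
            attr = "class_" if rank == "class" else rank
            setattr(rec, attr, resolution.higher_taxonomy.get(rank, ""))
        best = resolution.per_authority_best
        ids = [c.record.identifier if c else "" for c in best.values()]
        ext.authorityAIdentifier = ids[0] if ids else ""
        ext.authorityBIdentifier = ids[1] if len(ids) > 1 else ""
        accepted = best.get(resolution.accepted_authority)
        ext.matchScore = f"{accepted.score:.4f}" if accepted else ""
        ext.taxonResolutionMethod = (
            f"{resolution.resolution_method}; "
            f"match_type={accepted.match_type if accepted else 'n/a'}"
        )
        ext.consensusClass = resolution.consensus
    else:
        rec.scientificName = triplet.taxon.formal
        rec.identificationRemarks = "unresolved"
        ext.taxonResolutionMethod = (
            resolution.resolution_method if resolution else "not attempted"
        )
        ext.consensusClass = resolution.consensus if resolution else ""
    return rec, ext


def assign_identifiers(
    records: list[DarwinCoreRecord],
    notebook_id: str,
    revision_fingerprint: str = "",
) -> list[DarwinCoreRecord]:
    """Assign catalog numbers and stable occurrenceIDs in extraction order.

    catalogNumber is a notebook-scoped sequence.  occurrenceID hashes the
    record's immutable source coordinates — (notebook, page, character
    offset) — so unchanged pages always re-derive
    identical IDs and appended annotations never disturb earlier ones.
    ``revision_fingerprint`` is recorded by the caller in provenance, not
    hashed, precisely to preserve that stability.
    """
    seen: set[str] = set()
    for i, rec in enumerate(records, start=1):
        rec.catalogNumber = f"{notebook_id}-{i:04d}"
        key = f"{notebook_id}|{rec.page_number}|{rec.char_offset}"
        digest = hashlib.sha1(key.encode("utf-8")).hexdigest()[:20]
        rec.occurrenceID = f"urn:wikifieldnotes:{notebook_id}:{digest}"
        if rec.occurrenceID in seen:
            raise IntegrityError(
                f"duplicate occurrenceID for page {rec.page_number} "
                f"offset {rec.char_offset}"
            )
        seen.add(rec.occurrenceID)
    return records


def build_meta_xml(manifest: ArchiveManifest) -> bytes:
    """Render the archive descriptor; column indices follow the manifest."""
    ns = "http://rs.tdwg.org/dwc/text/"
    root = etree.Element(f"{{{ns}}}archive", nsmap={None: ns})
    core = etree.SubElement(
        root, f"{{{ns}}}core",
        rowType=manifest.row_type,
        fieldsTerminatedBy=manifest.fields_terminated_by,
        linesTerminatedBy="\\n",
        encoding=manifest.encoding,
        ignoreHeaderLines="1",
    )
    files_el = etree.SubElement(core, f"{{{ns}}}files")
    loc = etree.SubElement(files_el, f"{{{ns}}}location")
    loc.text = manifest.core_file
    etree.SubElement(core, f"{{{ns}}}id", index="0")
    for index, uri in enumerate(manifest.term_uris.values()):
        etree.SubElement(core, f"{{{ns}}}field", index=str(index), term=uri)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


_EML_STUB = """<?xml version="1.0" encoding="UTF-8"?>
<eml:eml xmlns:eml="eml://ecoinformatics.org/eml-2.1.1" packageId="{pkg}" system="wikifieldnotes">
  <dataset>
    <title>{title}</title>
    <abstract><para>Species occurrence records extracted from annotated
    field-notebook transcriptions.</para></abstract>
  </dataset>
</eml:eml>
"""


def write_outputs(
    records: list[DarwinCoreRecord],
    extensions: list[ProvenanceExtension],
    out_dir,
    manifest: ArchiveManifest | None = None,
    dataset_title: str = "Field notebook occurrences",
) -> dict[str, Path]:
    """Write simple CSV, full CSV, and the Darwin Core Archive zip.

    All files are UTF-8 with a header row; the archive core is
    tab-delimited as declared in meta.xml.  Returns the written paths.
    """
    if len(records) != len(extensions):
        raise IntegrityError("records and extensions must be parallel lists")
    manifest = manifest or ArchiveManifest()
    if list(manifest.term_uris) != DarwinCoreRecord.term_fields():
        raise IntegrityError("manifest term list disagrees with record layout")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    simple_path = out_dir / "occurrences_simple.csv"
    full_path = out_dir / "occurrences_full.csv"
    archive_path = out_dir / "dwca.zip"

    header = DarwinCoreRecord.header()
    with open(simple_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            writer.writerow(rec.row())

    with open(full_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header + ProvenanceExtension.columns())
        for rec, ext in zip(records, extensions):
            writer.writerow(rec.row() + ext.row())

    core = io.StringIO()
    core.write("\t".join(header) + "\n")
    for rec in records:
        cells = [c.replace("\t", " ").replace("\n", " ") for c in rec.row()]
        core.write("\t".join(cells) + "\n")

    with zipfile.ZipFile(archive_path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(manifest.core_file, core.getvalue())
        zf.writestr("meta.xml", build_meta_xml(manifest))
        zf.writestr("eml.xml", _EML_STUB.format(pkg=dataset_title.replace(" ", "-"),
                                                title=dataset_title))

    return {"simple": simple_path, "full": full_path, "archive": archive_path}
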