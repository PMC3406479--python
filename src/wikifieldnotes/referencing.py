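"""Taxonomic referencing: resolve annotators' names against two authorities.

Annotators interpret notebook text into formal names that freely mix
scientific binomials, genera, and vernacular names ("siskins", "mouse").
Each query is normalized (editorial brackets and "[sic]" stripped, trivial
plurals singularized), matched independently against two offline
name-authority snapshots — an EOL-like and an ITIS-like list in this
package's fixtures — and the two best candidates are compared:

* both agree (scientific name and kingdom) -> *consistent*, accepted;
* only one matches, or an expert decisions file picks a side -> that
  authority preferred;
* neither matches, or they disagree without an expert decision -> the
  query stays *unresolved* and is surfaced for review, never silently
  accepted (vernacular resolution is the error-prone path: one live
  service famously mapped "mouse" to the mouse moth *Amphipyra
  tragopoginis*).

Matching scores: exact scientific 1.0, exact vernacular 0.9, fuzzy
1 − d/max(|query|, |name|) for edit distance d within a configured
threshold.  Homonyms across kingdoms (*Crucibulum* the gastropod vs the
fungus) are never merged: kingdom is part of candidate identity.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .errors import ConfigurationError, IntegrityError

__all__ = [
    "AuthorityRecord",
    "Authority",
    "Candidate",
    "ResolutionResult",
    "ReconcileConfig",
    "HIGHER_RANKS",
    "load_authority",
    "load_decisions",
    "normalize_name",
    "match_name",
    "reconcile",
    "attach_taxonomy",
    "bundled_authority_path",
]

HIGHER_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

CONSENSUS_CONSISTENT = "consistent"
CONSENSUS_A = "authority_a_preferred"
CONSENSUS_B = "authority_b_preferred"
CONSENSUS_UNRESOLVED = "unresolved"


@dataclass
class AuthorityRecord:
    authority_id: str
    identifier: str
    name: str
    rank: str
    accepted: bool
    vernaculars: list[str]
    higher_taxonomy: dict[str, str]


@dataclass
class Candidate:
    record: AuthorityRecord
    score: float
    match_type: str  # exact_scientific | exact_vernacular | fuzzy_scientific | fuzzy_vernacular

    def sort_key(self):
        # score desc, accepted first, then identifier for stable ties
        return (-self.score, not self.record.accepted, self.record.identifier)


class Authority:
    """One loaded name-authority snapshot with lookup indexes."""

    def __init__(self, authority_id: str, records: list[AuthorityRecord]):
        self.authority_id = authority_id
        self.records = records
        self.by_identifier: dict[str, AuthorityRecord] = {}
        self.by_scientific: dict[str, list[AuthorityRecord]] = {}
        self.by_vernacular: dict[str, list[AuthorityRecord]] = {}
        for rec in records:
            if rec.identifier in self.by_identifier:
                raise IntegrityError(
                    f"{authority_id}: duplicate identifier {rec.identifier!r}"
                )
            self.by_identifier[rec.identifier] = rec
            self.by_scientific.setdefault(normalize_name(rec.name), []).append(rec)
            for v in rec.vernaculars:
                self.by_vernacular.setdefault(normalize_name(v), []).append(rec)


def bundled_authority_path(label: str) -> Path:
    """Path of a bundled synthetic authority snapshot ("eol" or "itis")."""
    name = f"authority_{label.lower()}_synthetic.tsv"
    path = Path(__file__).parent / "data" / name
    if not path.exists():
        raise ConfigurationError(f"no bundled authority snapshot {label!r}")
    return path


def load_authority(path, authority_id: str | None = None) -> Authority:
    """Load a TSV snapshot: identifier, scientific_name, rank, accepted,
    vernaculars (pipe-separated), kingdom..genus."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"authority snapshot {path} not found")
    records: list[AuthorityRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        label = authority_id or path.stem
        for row in reader:
            records.append(AuthorityRecord(
                authority_id=label,
                identifier=row["identifier"],
                name=row["scientific_name"],
                rank=row["rank"],
                accepted=row["accepted"].strip().lower() in ("1", "true", "yes"),
                vernaculars=[v for v in row["vernaculars"].split("|") if v],
                higher_taxonomy={
                    rank: row.get(rank, "") for rank in HIGHER_RANKS if row.get(rank)
                },
            ))
    return Authority(label, records)


_SIC_RE = re.compile(r"\[\s*sic\s*\]", re.IGNORECASE)
_PLURAL_KEEP_SUFFIXES = ("ss", "us", "is")


def _singularize(word: str) -> str:
    if len(word) > 3 and word.endswith("s") and not word.endswith(_PLURAL_KEEP_SUFFIXES):
        return word[:-1]
    return word


def normalize_name(text: str) -> str:
    """Normalize a name for matching.

    Drops "[sic]", unwraps other editorial brackets ("[American] Robins"
    keeps "American"), collapses whitespace, lowercases, and singularizes
    the head noun by a trivial rule list ("robins" -> "robin"; Latin
    endings -us/-is are left alone).
    """
    cleaned = _SIC_RE.sub(" ", text)
    cleaned = cleaned.replace("[", " ").replace("]", " ")
    words = cleaned.lower().split()
    if not words:
        raise ValueError(f"name {text!r} is empty after normalization")
    words[-1] = _singularize(words[-1])
    return " ".join(words)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def match_name(
    authority: Authority,
    query: str,
    fuzzy_threshold: int = 2,
    fuzzy_vernacular_threshold: int | None = None,
) -> list[Candidate]:
    """Rank authority records against a normalized query.

    Exact scientific hits score 1.0, exact vernacular hits 0.9 (mapped to
    their scientific record).  When no exact hit exists, fuzzy scientific
    matching applies within ``fuzzy_threshold`` edits; fuzzy vernacular
    matching is opt-in via ``fuzzy_vernacular_threshold`` (vernaculars are
    the error-prone path).  Ties rank accepted records first, then by
    identifier.  Empty list means no match.
    """
    candidates: list[Candidate] = []
    seen: set[tuple[str, str]] = set()

    def add(rec: AuthorityRecord, score: float, match_type: str) -> None:
        key = (rec.identifier, match_type.split("_")[-1])
        if key not in seen:
            seen.add(key)
            candidates.append(Candidate(rec, score, match_type))

    for rec in authority.by_scientific.get(query, []):
        add(rec, 1.0, "exact_scientific")
    for rec in authority.by_vernacular.get(query, []):
        add(rec, 0.9, "exact_vernacular")

    if not candidates:
        for norm, recs in authority.by_scientific.items():
            dist = _edit_distance(query, norm)
            if 0 < dist <= fuzzy_threshold:
                score = 1.0 - dist / max(len(query), len(norm))
                for rec in recs:
                    add(rec, score, "fuzzy_scientific")
        if fuzzy_vernacular_threshold is not None:
            for norm, recs in authority.by_vernacular.items():
                dist = _edit_distance(query, norm)
                if 0 < dist <= fuzzy_vernacular_threshold:
                    score = 0.9 * (1.0 - dist / max(len(query), len(norm)))
                    for rec in recs:
                        add(rec, score, "fuzzy_vernacular")

    candidates.sort(key=Candidate.sort_key)
    return candidates


@dataclass
class ReconcileConfig:
    """Reconciliation policy.

    ``decisions`` externalizes expert adjudication of disagreements as data:
    normalized query -> one of "A", "B", "both", "neither".  ``fuzzy_threshold``
    bounds scientific-name edit distance; vernacular fuzzy matching is off
    unless ``fuzzy_vernacular_threshold`` is set (recommended 1).
    """

    decisions: dict[str, str] = field(default_factory=dict)
    fuzzy_threshold: int = 2
    fuzzy_vernacular_threshold: int | None = None


@dataclass
class ResolutionResult:
    query_verbatim: str
    normalized_query: str
    per_authority_best: dict[str, Candidate | None]
    consensus: str
    accepted_name: str | None
    accepted_identifier: str | None
    accepted_authority: str | None
    resolution_method: str
    review_needed: bool = False
    candidates: dict[str, list[Candidate]] = field(default_factory=dict)
    higher_taxonomy: dict[str, str] = field(default_factory=dict)
    vernacular_name: str = ""


def load_decisions(path) -> dict[str, str]:
    """Load an expert decisions TSV (normalized_query, chosen_authority)."""
    decisions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            query, choice = line.split("\t")[:2]
            if choice not in ("A", "B", "both", "neither"):
                raise ConfigurationError(
                    f"decision for {query!r} must be A/B/both/neither, got {choice!r}"
                )
            decisions[query] = choice
    return decisions


def _accepted_form(cand: Candidate) -> tuple[str, str]:
    """Identity of a candidate's accepted name: (scientific name, kingdom).

    Kingdom participates so cross-kingdom homonyms never merge.
    """
    return (normalize_name(cand.record.name),
            cand.record.higher_taxonomy.get("kingdom", ""))


def _unambiguous_best(candidates: list[Candidate]) -> tuple[Candidate | None, bool]:
    """Top candidate, or None-with-ambiguity when the top score ties across
    distinct accepted names (e.g. a vernacular shared by 18 species)."""
    if not candidates:
        return None, False
    best = candidates[0]
    tied_names = {
        _accepted_form(c)
        for c in candidates
        if c.score == best.score and c.record.accepted == best.record.accepted
    }
    if len(tied_names) > 1:
        return None, True
    return best, False


def reconcile(
    query: str,
    authority_a: Authority,
    authority_b: Authority,
    config: ReconcileConfig | None = None,
) -> ResolutionResult:
    """Resolve one formal name against two authorities and classify consensus.

    Pure function of (query, snapshots, decisions): repeated runs are
    identical.  Disagreements without an expert decision are flagged for
    review and left unresolved rather than auto-accepted.
    """
    config = config or ReconcileConfig()
    normalized = normalize_name(query)

    cands = {}
    best = {}
    ambiguous = {}
    for auth in (authority_a, authority_b):
        ranked = match_name(auth, normalized, config.fuzzy_threshold,
                            config.fuzzy_vernacular_threshold)
        cands[auth.authority_id] = ranked
        best[auth.authority_id], ambiguous[auth.authority_id] = _unambiguous_best(ranked)

    a_id, b_id = authority_a.authority_id, authority_b.authority_id
    best_a, best_b = best[a_id], best[b_id]

    consensus = CONSENSUS_UNRESOLVED
    accepted: Candidate | None = None
    accepted_from: str | None = None
    method = "unresolved"
    review = False

    if best_a is not None and best_b is not None:
        if _accepted_form(best_a) == _accepted_form(best_b):
            consensus, accepted, accepted_from = CONSENSUS_CONSISTENT, best_a, a_id
            method = f"{a_id} & {b_id}"
        else:
            choice = config.decisions.get(normalized)
            if choice == "A":
                consensus, accepted, accepted_from = CONSENSUS_A, best_a, a_id
                method = f"{a_id} (expert choice)"
            elif choice == "B":
                consensus, accepted, accepted_from = CONSENSUS_B, best_b, b_id
                method = f"{b_id} (expert choice)"
            elif choice == "both":
                consensus, accepted, accepted_from = CONSENSUS_CONSISTENT, best_a, a_id
                method = f"{a_id} & {b_id} (expert: both)"
            elif choice == "neither":
                method = "unresolved (expert: neither)"
            else:
                method = "unresolved (disagreement pending review)"
                review = True
    elif best_a is not None:
        consensus, accepted, accepted_from = CONSENSUS_A, best_a, a_id
        method = a_id
    elif best_b is not None:
        consensus, accepted, accepted_from = CONSENSUS_B, best_b, b_id
        method = b_id
    elif ambiguous[a_id] or ambiguous[b_id]:
        method = "unresolved (ambiguous match)"
        review = True

    return ResolutionResult(
        query_verbatim=query,
        normalized_query=normalized,
        per_authority_best=best,
        consensus=consensus,
        accepted_name=accepted.record.name if accepted else None,
        accepted_identifier=accepted.record.identifier if accepted else None,
        accepted_authority=accepted_from,
        resolution_method=method,
        review_needed=review,
        candidates=cands,
    )


def attach_taxonomy(
    result: ResolutionResult,
    authority_a: Authority,
    authority_b: Authority,
    prefer: str | None = None,
) -> ResolutionResult:
    """Copy higher taxonomy and preferred vernacular onto a resolved result.

    Taxonomy comes from the authority that accepted the name; for
    consistent results the identifier-bearing reference authority (the
    second, ITIS-like snapshot) is preferred when it participated, since
    its serial numbers anchor the vernacularName and higher-taxonomy
    fields.  Unresolved results pass through unchanged.
    """
    if result.accepted_name is None:
        return result
    authorities = {a.authority_id: a for a in (authority_a, authority_b)}

    source_id = result.accepted_authority
    if result.consensus == CONSENSUS_CONSISTENT:
        preferred = prefer or authority_b.authority_id
        if result.per_authority_best.get(preferred) is not None:
            source_id = preferred
    cand = result.per_authority_best.get(source_id)
    if cand is None or source_id not in authorities:
        raise IntegrityError(
            f"accepted authority {source_id!r} has no candidate for "
            f"{result.normalized_query!r}"
        )
    rec = authorities[source_id].by_identifier.get(cand.record.identifier)
    if rec is None:
        raise IntegrityError(
            f"identifier {cand.record.identifier!r} missing from {source_id}"
        )
    result.higher_taxonomy = dict(rec.higher_taxonomy)
    result.vernacular_name = rec.vernaculars[0] if rec.vernaculars else ""
    return result
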