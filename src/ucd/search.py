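"""Structure search over the registration area: exact, substructure and
similarity.

Exact search matches on the ratio-stripped identity key, so every mixture
ratio of one enantiomer mixture — and every tautomer drawing of one molecule
— retrieves the same set of entries.  Substructure search is subgraph
matching with a pattern-fingerprint prescreen that can only discard
guaranteed non-matches (no false negatives).  Similarity search ranks by the
Tanimoto coefficient over hashed topological path fingerprints (2048 bits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from rdkit import Chem, DataStructs

from ucd import _rdkit
from ucd import standardizer as _std
from ucd.chem_model import StructureRecord
from ucd.registry import Registry

__all__ = [
    "SearchHit",
    "SearchError",
    "exact_search",
    "substructure_search",
    "similarity_search",
    "FINGERPRINT_BITS",
]

FINGERPRINT_BITS = 2048


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SearchHit:
    """One matching molecule with its substances and batches.  ``score`` is
    the Tanimoto coefficient in similarity mode and 1.0 otherwise."""

    molecule_code: str
    substances: Tuple[str, ...]
    batches: Tuple[int, ...]
    score: float = 1.0


def _hit(reg: Registry, code: str, include_archived: bool, score: float = 1.0):
    subs = []
    batches = []
    for s in reg.substances.values():
        if s.molecule_code != code:
            continue
        if s.status == "archived" and not include_archived:
            continue
        subs.append(s.code)
        for b in reg.batches_of_substance(s.code):
            if b.status == "archived" and not include_archived:
                continue
            batches.append(b.code)
    return SearchHit(code, tuple(sorted(subs)), tuple(sorted(batches)), score)


def _candidates(reg: Registry, include_archived: bool):
    for code, mol in sorted(reg.molecules.items()):
        if mol.no_structure:
            continue
        if mol.status == "archived" and not include_archived:
            continue
        yield code, mol


def _query_record(query) -> StructureRecord:
    if isinstance(query, StructureRecord):
        return query
    return _std.parse_structure(query)


def _cached_mol(reg: Registry, code: str):
    cache = reg._search_cache.setdefault("mols", {})
    if code not in cache:
        mol, problems = _rdkit.record_to_mol(
            reg.molecules[code].structure, need_conformer=False
        )
        cache[code] = mol if not problems else None
    return cache[code]


def _cached_fp(reg: Registry, kind: str, code: str):
    cache = reg._search_cache.setdefault(kind, {})
    if code not in cache:
        mol = _cached_mol(reg, code)
        if mol is None:
            cache[code] = None
        elif kind == "pattern":
            cache[code] = Chem.PatternFingerprint(mol)
        else:
            cache[code] = Chem.RDKFingerprint(mol, fpSize=FINGERPRINT_BITS)
    return cache[code]


# ---------------------------------------------------------------------------


def exact_search(
    reg: Registry, query, include_archived: bool = False
) -> List[SearchHit]:
    """Every molecule whose structure-only key (mixture ratio stripped)
    equals the standardized query's."""
    record = _query_record(query)
    if record.no_structure:
        raise SearchError("a No Structure query has nothing to match")
    normalized = _std.standardize(record)
    key = _std.structure_key(normalized.structure)
    hits = []
    for code, mol in _candidates(reg, include_archived):
        if reg._structure_key.get(code) == key:
            hits.append(_hit(reg, code, include_archived))
    return hits


def substructure_search(
    reg: Registry, query, include_archived: bool = False
) -> List[SearchHit]:
    """All molecules containing the query as a subgraph.  Stereochemistry is
    only enforced when the query itself carries wedges."""
    record = _query_record(query)
    if record.no_structure or record.num_atoms == 0:
        raise SearchError("empty substructure query")
    qmol, problems = _rdkit.record_to_mol(record, need_conformer=False)
    if problems:
        raise SearchError("substructure query is not a valid pattern")
    use_chirality = any(b.wedge in ("up", "down") for b in record.bonds)
    qfp = Chem.PatternFingerprint(qmol)
    hits = []
    for code, mol in _candidates(reg, include_archived):
        tfp = _cached_fp(reg, "pattern", code)
        if tfp is None:
            continue
        # prescreen: every query bit must be present in the target
        if (qfp & tfp).GetNumOnBits() != qfp.GetNumOnBits():
            continue
        target = _cached_mol(reg, code)
        if target is not None and target.HasSubstructMatch(
            qmol, useChirality=use_chirality
        ):
            hits.append(_hit(reg, code, include_archived))
    return hits


def similarity_search(
    reg: Registry,
    query,
    threshold: float = 0.7,
    include_archived: bool = False,
) -> List[SearchHit]:
    """Molecules with Tanimoto similarity >= threshold, sorted by descending
    score with ties broken by molecule code."""
    if not 0.0 <= threshold <= 1.0:
        raise SearchError(f"threshold must be within [0, 1], got {threshold}")
    record = _query_record(query)
    if record.no_structure:
        raise SearchError("a No Structure query has no fingerprint")
    qmol, problems = _rdkit.record_to_mol(record, need_conformer=False)
    if problems:
        raise SearchError("similarity query is not a valid structure")
    qfp = Chem.RDKFingerprint(qmol, fpSize=FINGERPRINT_BITS)
    scored = []
    for code, mol in _candidates(reg, include_archived):
        tfp = _cached_fp(reg, "rdk", code)
        if tfp is None:
            continue
        score = DataStructs.TanimotoSimilarity(qfp, tfp)
        if score >= threshold:
            scored.append((score, code))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [_hit(reg, code, include_archived, score) for score, code in scored]
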