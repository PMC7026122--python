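"""FASTA I/O, decoy generation, in-silico digestion and enumeration of
variably modified candidate oligonucleotides."""

from __future__ import annotations

import itertools
import random
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .chem_core import (
    ChemistryError,
    Modification,
    ModificationRegistry,
    NASequence,
    TerminusChemistry,
    default_registry,
    parse_sequence,
    sequence_mass,
)

__all__ = [
    "FastaRecord",
    "DigestProduct",
    "ModifiedCandidate",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "generate_decoys",
    "digest_rnase_t1",
    "digest_unspecific",
    "enumerate_modifications",
    "build_candidates",
    "DECOY_PREFIX",
]

DECOY_PREFIX = "DECOY_"


class FastaError(ValueError):
    pass


@dataclass(frozen=True)
class FastaRecord:
    identifier: str
    description: str
    sequence: str  # A/C/G/U plus bracketed modification codes, optional 'p'

    @property
    def is_decoy(self) -> bool:
        return self.identifier.startswith(DECOY_PREFIX)


_LEGAL_SEQ = re.compile(r"^([ACGUT]|\[[^\]\[]+\])+p?$")


def read_fasta(path) -> List[FastaRecord]:
    """Read an RNA FASTA file; ``T`` is transliterated to ``U`` with a warning."""
    records: List[FastaRecord] = []
    seen = set()
    header: Optional[Tuple[str, str]] = None
    chunks: List[str] = []
    header_line = 0

    def flush(lineno):
        nonlocal header, chunks
        if header is None:
            return
        ident, desc = header
        seq = "".join(chunks)
        if not seq:
            raise FastaError(f"record {ident!r} (line {header_line}) has empty sequence")
        if not _LEGAL_SEQ.match(seq):
            raise FastaError(
                f"record {ident!r} (line {header_line}): illegal residue characters"
            )
        if "T" in seq:
            warnings.warn(f"record {ident!r}: transliterating T to U")
            seq = seq.replace("T", "U")
        records.append(FastaRecord(ident, desc, seq))
        header, chunks = None, []

    with open(path, "rt", encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                parts = line[1:].split(None, 1)
                if not parts:
                    raise FastaError(f"line {lineno}: empty FASTA header")
                ident = parts[0]
                if ident in seen:
                    raise FastaError(f"line {lineno}: duplicate identifier {ident!r}")
                seen.add(ident)
                header = (ident, parts[1] if len(parts) > 1 else "")
                header_line = lineno
            else:
                if header is None:
                    raise FastaError(f"line {lineno}: sequence data before first header")
                chunks.append(line)
        flush(lineno)
    if not records:
        raise FastaError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[FastaRecord], path, width: int = 70) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.identifier}{desc}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# tokens: one plain residue or one bracketed modified residue
_TOKEN = re.compile(r"[ACGU]|\[[^\]\[]+\]")


def _tokenize(seq: str) -> List[str]:
    """Split a bracketed sequence string into per-residue tokens."""
    body = seq[:-1] if seq.endswith("p") else seq
    return [m.group(0) for m in _TOKEN.finditer(body)]


def generate_decoys(records: Sequence[FastaRecord], method: str = "reverse",
                    seed: Optional[int] = None) -> List[FastaRecord]:
    """One decoy per target: reversed or shuffled residue tokens.

    Bracketed modifications travel with their residue.  Shuffling requires a
    seed for reproducibility.
    """
    if method not in ("shuffle", "reverse"):
        raise ValueError(f"unknown decoy method {method!r}")
    if method == "shuffle" and seed is None:
        raise ValueError("shuffle decoys require a seed")
    rng = random.Random(seed)
    decoys = []
    for rec in records:
        tokens = _tokenize(rec.sequence)
        if method == "reverse":
            tokens = tokens[::-1]
        else:
            rng.shuffle(tokens)
        suffix = "p" if rec.sequence.endswith("p") else ""
        decoys.append(FastaRecord(DECOY_PREFIX + rec.identifier,
                                  rec.description, "".join(tokens) + suffix))
    return decoys


@dataclass(frozen=True)
class DigestProduct:
    parent_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: NASequence
    missed_cleavages: int = 0

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinate span does not match sequence length")


def digest_rnase_t1(parent: NASequence, max_missed_cleavages: int = 0,
                    parent_id: str = "", min_length: int = 1,
                    cleave_modified_g: bool = True) -> List[DigestProduct]:
    """In-silico RNase T1 digest: cleave 3' of every guanosine.

    Products acquire a 3'-phosphate and a 5'-hydroxyl at internal cut sites;
    the terminal products inherit the parent terminus on their uncut side.
    ``max_missed_cleavages`` counts skipped internal G sites.
    """
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    n = len(parent)
    modmap = parent.modification_map
    sites = []  # cleave after these 1-based positions
    for i, r in enumerate(parent.residues, 1):
        if r != "G":
            continue
        if i in modmap and not cleave_modified_g:
            continue
        if i < n:  # a cut at the parent 3' end is a no-op
            sites.append(i)
    boundaries = [0] + sites + [n]
    products: List[DigestProduct] = []
    for a_idx in range(len(boundaries) - 1):
        for b_idx in range(a_idx + 1, len(boundaries)):
            missed = b_idx - a_idx - 1
            if missed > max_missed_cleavages:
                break
            start = boundaries[a_idx] + 1
            end = boundaries[b_idx]
            if end - start + 1 < min_length:
                continue
            five = parent.termini.five_prime if start == 1 else "hydroxyl"
            three = parent.termini.three_prime if end == n else "phosphate"
            sub = parent.subsequence(start, end, TerminusChemistry(five, three))
            products.append(DigestProduct(parent_id, start, end, sub, missed))
    return products


def digest_unspecific(parent: NASequence, min_len: int, max_len: int,
                      parent_id: str = "") -> List[DigestProduct]:
    """All contiguous subsequences within the length bounds.

    Internal substrings get 5'-OH/3'-OH (synthesis artefacts rather than
    enzymatic products); substrings touching a parent end inherit that
    terminus.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError(f"bad length bounds {min_len}..{max_len}")
    n = len(parent)
    products = []
    for start in range(1, n + 1):
        for end in range(start + min_len - 1, min(n, start + max_len - 1) + 1):
            five = parent.termini.five_prime if start == 1 else "hydroxyl"
            three = parent.termini.three_prime if end == n else "hydroxyl"
            sub = parent.subsequence(start, end, TerminusChemistry(five, three))
            products.append(DigestProduct(parent_id, start, end, sub, 0))
    return products


@dataclass(frozen=True)
class ModifiedCandidate:
    """A digestion product with a concrete modification placement."""

    product: DigestProduct
    sequence: NASequence
    neutral_mass: float
    is_decoy: bool = False
    locations: Tuple[Tuple[str, int, int], ...] = ()  # (parent_id, start, end)

    @property
    def key(self) -> str:
        return self.sequence.to_string(show_placement=True)

    def n_variable_mods(self) -> int:
        return self.sequence.n_modifications() - self.product.sequence.n_modifications()


def enumerate_modifications(product: DigestProduct,
                            variable_mods: Sequence[Modification],
                            fixed_mods: Sequence[Modification] = (),
                            max_mods: int = 0) -> List[ModifiedCandidate]:
    """All placements of up to ``max_mods`` variable modifications.

    One modification per position; inline (database-annotated) and fixed
    modifications block their positions.  For placement="either" mods both a
    base-placed and a sugar-placed variant are produced, except at the
    3'-terminal residue where no a-B ion can discriminate them (a single
    base-placed candidate is kept there).
    """
    if max_mods < 0:
        raise ValueError("max_mods must be >= 0")
    seq = product.sequence
    n = len(seq)
    base_mods = list(seq.modifications)
    occupied = {pos for pos, _, _ in base_mods}

    # apply fixed mods first
    for fmod in fixed_mods:
        hit = False
        for i, r in enumerate(seq.residues, 1):
            if i in occupied:
                continue
            if r in fmod.target_bases:
                placement = "sugar" if fmod.placement == "sugar" else "base"
                base_mods.append((i, fmod, placement))
                occupied.add(i)
                hit = True
        if not hit and all(r not in fmod.target_bases for r in seq.residues):
            pass  # no eligible residue in this product: fixed mod simply absent
    fixed_positions = set(occupied)

    # per-position options for variable mods
    site_options: List[Tuple[int, List[Tuple[Modification, str]]]] = []
    for i, r in enumerate(seq.residues, 1):
        if i in occupied:
            continue
        opts: List[Tuple[Modification, str]] = []
        for vmod in variable_mods:
            if r not in vmod.target_bases:
                continue
            if vmod.placement == "either" and i < n:
                opts.append((vmod, "base"))
                opts.append((vmod, "sugar"))
            elif vmod.placement == "sugar":
                opts.append((vmod, "sugar"))
            else:
                opts.append((vmod, "base"))
        if opts:
            site_options.append((i, opts))

    candidates: List[ModifiedCandidate] = []
    positions = [p for p, _ in site_options]
    options = {p: o for p, o in site_options}
    for k in range(0, min(max_mods, len(positions)) + 1):
        for combo in itertools.combinations(positions, k):
            for choice in itertools.product(*(options[p] for p in combo)):
                mods = tuple(base_mods) + tuple(
                    (p, m, pl) for p, (m, pl) in zip(combo, choice))
                new_seq = NASequence(seq.residues, mods, seq.termini)
                candidates.append(ModifiedCandidate(
                    product=product,
                    sequence=new_seq,
                    neutral_mass=sequence_mass(new_seq),
                    locations=((product.parent_id, product.start, product.end),),
                ))
    return candidates


def _digest_record(rec: FastaRecord, registry: ModificationRegistry,
                   digestion: str, **kw) -> List[DigestProduct]:
    parent = parse_sequence(rec.sequence, registry)
    if digestion == "rnase_t1":
        return digest_rnase_t1(parent,
                               max_missed_cleavages=kw.get("missed_cleavages", 0),
                               parent_id=rec.identifier,
                               min_length=kw.get("min_length", 1),
                               cleave_modified_g=kw.get("cleave_modified_g", True))
    if digestion == "unspecific":
        return digest_unspecific(parent, kw.get("min_length", 5),
                                 kw.get("max_length", 40),
                                 parent_id=rec.identifier)
    if digestion == "none":
        return [DigestProduct(rec.identifier, 1, len(parent), parent, 0)]
    raise ValueError(f"unknown digestion mode {digestion!r}")


def build_candidates(records: Sequence[FastaRecord],
                     variable_mods: Sequence[Modification] = (),
                     fixed_mods: Sequence[Modification] = (),
                     max_mods: int = 0,
                     digestion: str = "rnase_t1",
                     registry: Optional[ModificationRegistry] = None,
                     **digest_kw) -> List[ModifiedCandidate]:
    """Digest + enumerate a whole database; deduplicate identical oligos.

    Oligonucleotides that occur in multiple database entries (or multiple
    positions) are kept once per distinct (sequence, termini) with the full
    location list.  Target/decoy status is tracked per record prefix; a
    sequence present in both target and decoy space counts as target.
    """
    if registry is None:
        registry = default_registry()
    merged: Dict[Tuple[str, bool], ModifiedCandidate] = {}
    for rec in records:
        for product in _digest_record(rec, registry, digestion, **digest_kw):
            for cand in enumerate_modifications(product, variable_mods,
                                                fixed_mods, max_mods):
                key = (cand.key, rec.is_decoy)
                if key in merged:
                    prev = merged[key]
                    merged[key] = ModifiedCandidate(
                        product=prev.product, sequence=prev.sequence,
                        neutral_mass=prev.neutral_mass, is_decoy=rec.is_decoy,
                        locations=prev.locations + cand.locations)
                else:
                    merged[key] = ModifiedCandidate(
                        product=cand.product, sequence=cand.sequence,
                        neutral_mass=cand.neutral_mass, is_decoy=rec.is_decoy,
                        locations=cand.locations)
    return sorted(merged.values(), key=lambda c: c.neutral_mass)
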