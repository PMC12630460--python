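"""Structure standardization and fingerprinting backends.

The diversity metrics only need (a) a canonical structure string per
compound and (b) a binary fingerprint per structure; both are produced by
pluggable backends so the core package carries no hard chemistry
dependency.  Two backends are provided:

* :class:`RDKitBackend` — real chemistry.  Standardization strips salt and
  solvent fragments by keeping the fragment with the most heavy atoms and
  returns the canonical SMILES; fingerprints are hashed circular (Morgan)
  fingerprints, radius 2 over 2048 bits.
* :class:`HashedFingerprinter` — chemistry-free.  Treats structure strings
  as opaque identifiers and derives a deterministic sparse bit set from a
  cryptographic hash of the string; used for synthetic data.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Optional, Protocol

from .datamodel import Fingerprint

logger = logging.getLogger("phytodiv")


class StructureBackend(Protocol):
    def standardize(self, raw: str) -> Optional[str]: ...

    def fingerprint(self, structure: str) -> Fingerprint: ...


class RDKitBackend:
    """SMILES standardization and Morgan fingerprints via RDKit.

    Multi-fragment inputs (salts, solvates) are reduced to the single
    fragment with the most heavy atoms; ties are broken by the
    lexicographically smallest canonical SMILES so the choice is
    deterministic.  Unparseable input yields ``None`` with a warning
    rather than an exception, so bad records are droppable upstream.
    """

    def __init__(self, radius: int = 2, n_bits: int = 2048):
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdFingerprintGenerator

        RDLogger.DisableLog("rdApp.*")
        self._Chem = Chem
        self._gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        self.n_bits = n_bits

    def standardize(self, raw: str) -> Optional[str]:
        Chem = self._Chem
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            logger.warning("unparseable structure %r rejected", raw)
            return None
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        best = max(
            frags,
            key=lambda f: (f.GetNumHeavyAtoms(), _neg_lex(Chem.MolToSmiles(f))),
        )
        return Chem.MolToSmiles(best)

    def fingerprint(self, structure: str) -> Fingerprint:
        mol = self._Chem.MolFromSmiles(structure)
        if mol is None:
            raise ValueError(f"cannot fingerprint unparseable structure {structure!r}")
        fp = self._gen.GetFingerprint(mol)
        return Fingerprint(bits=frozenset(fp.GetOnBits()), n_bits=self.n_bits)


class _NegLex(str):
    """Reverses string ordering so max() picks the lexicographically smallest."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)

    def __le__(self, other):
        return str.__ge__(self, other)

    def __ge__(self, other):
        return str.__le__(self, other)


def _neg_lex(s: str) -> _NegLex:
    return _NegLex(s)


class HashedFingerprinter:
    """Deterministic pseudo-random sparse fingerprints from structure IDs.

    Bit indices are derived from SHA-256 of ``structure || counter``, giving
    ``n_on`` distinct bits in a ``n_bits`` space.  The same structure string
    always maps to the same fingerprint, in any process, with no seed —
    which keeps synthetic pipelines reproducible.  Standardization is the
    identity (synthetic IDs carry no fragments).
    """

    def __init__(self, n_bits: int = 2048, n_on: int = 64):
        if not 0 < n_on <= n_bits:
            raise ValueError("need 0 < n_on <= n_bits")
        self.n_bits = n_bits
        self.n_on = n_on

    def standardize(self, raw: str) -> Optional[str]:
        return raw if raw else None

    def fingerprint(self, structure: str) -> Fingerprint:
        bits: set[int] = set()
        counter = 0
        while len(bits) < self.n_on:
            h = hashlib.sha256(f"{structure}\x00{counter}".encode()).digest()
            for i in range(0, len(h) - 3, 4):
                bits.add(int.from_bytes(h[i : i + 4], "big") % self.n_bits)
                if len(bits) == self.n_on:
                    break
            counter += 1
        return Fingerprint(bits=frozenset(bits), n_bits=self.n_bits)


def standardize_structure(raw: str, backend: Optional[StructureBackend] = None) -> Optional[str]:
    """Standardize ``raw`` to a canonical parent-fragment structure string.

    Multi-fragment inputs keep only the largest fragment (most heavy
    atoms).  Idempotent: re-standardizing the output is a no-op.  Returns
    ``None`` (with a logged warning) for unparseable input.
    """
    if backend is None:
        backend = RDKitBackend()
    return backend.standardize(raw)
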