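"""Rule-based in-silico protease digestion.

Tests whether a peptide could be degraded by proteases expected in amniotic
fluid (pepsin, trypsin, chymotrypsin, Arg-C proteinase). Each enzyme is a
set of site rules over the residue N-terminal to the scissile bond (P1) and
the residue C-terminal to it (P1'); a rule may also block cleavage for
certain P1' residues (e.g. proline after a tryptic site).

Positions are 0-based bond indices: site ``i`` is the bond between residues
``i`` and ``i+1``. Bonds at the sequence termini (the bond after the first
residue and nothing beyond the last) are excluded by construction, so valid
sites lie strictly inside ``(0, len-1)``.

The built-in tables are deliberately simplified approximations of the
PeptideCutter specificities; full exception tables can be loaded from a YAML
rules file via :func:`load_rules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from .datamodel import AA_ALPHABET
from .errors import DataError, UsageError

_AA_SET = frozenset(AA_ALPHABET)


@dataclass(frozen=True)
class CleavageRule:
    """One site rule: optional P1 set, optional P1' set, optional P1' block."""

    p1: frozenset | None = None
    p1_prime: frozenset | None = None
    blocked_p1_prime: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.p1 is None and self.p1_prime is None:
            raise UsageError("a cleavage rule needs a P1 and/or P1' residue set")
        for s in (self.p1, self.p1_prime, self.blocked_p1_prime):
            if s is not None and not frozenset(s) <= _AA_SET:
                raise UsageError(f"residues outside the 20-letter alphabet: {set(s) - _AA_SET}")

    def matches(self, res_p1: str, res_p1_prime: str) -> bool:
        if self.p1 is not None and res_p1 not in self.p1:
            return False
        if self.p1_prime is not None and res_p1_prime not in self.p1_prime:
            return False
        return res_p1_prime not in self.blocked_p1_prime


@dataclass(frozen=True)
class CleavageRuleSet:
    name: str
    rules: tuple[CleavageRule, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.rules:
            raise UsageError(f"enzyme '{self.name}' has no rules")


def _rs(p1=None, p1_prime=None, blocked=()) -> CleavageRule:
    return CleavageRule(
        p1=frozenset(p1) if p1 else None,
        p1_prime=frozenset(p1_prime) if p1_prime else None,
        blocked_p1_prime=frozenset(blocked),
    )


#: Simplified specificities. Trypsin: after K/R unless P follows. Chymotrypsin
#: (high specificity): after F/Y/W unless P follows. Arg-C: after R. Pepsin
#: pH>2: F or L on either side of the bond; pH 1.3: F or L at P1 only.
BUILTIN_ENZYMES: dict[str, CleavageRuleSet] = {
    "trypsin": CleavageRuleSet("trypsin", (_rs(p1="KR", blocked="P"),)),
    "chymotrypsin": CleavageRuleSet("chymotrypsin", (_rs(p1="FYW", blocked="P"),)),
    "arg_c": CleavageRuleSet("arg_c", (_rs(p1="R"),)),
    "pepsin_ph_gt2": CleavageRuleSet(
        "pepsin_ph_gt2", (_rs(p1="FL"), _rs(p1_prime="FL"))
    ),
    "pepsin_ph1_3": CleavageRuleSet("pepsin_ph1_3", (_rs(p1="FL"),)),
}

#: Enzyme panel expected in amniotic fluid.
AF_PANEL = ("pepsin_ph_gt2", "trypsin", "chymotrypsin", "arg_c")


def get_enzyme(name: str) -> CleavageRuleSet:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise UsageError(
            f"unknown enzyme '{name}'; built-ins: {sorted(BUILTIN_ENZYMES)}"
        ) from None


def _check_sequence(sequence: str) -> str:
    seq = str(sequence).upper()
    if len(seq) < 2:
        raise UsageError("sequence must have at least 2 residues")
    for i, ch in enumerate(seq):
        if ch not in _AA_SET:
            raise DataError(f"invalid residue '{ch}' at position {i}")
    return seq


def cleavage_sites(sequence: str, rules: CleavageRuleSet | str) -> list[int]:
    """Ascending 0-based bond indices cleaved by an enzyme.

    Only strictly internal bonds are considered: indices run from 1 to
    ``len(sequence) - 2`` inclusive, so a cut never sits at a terminus.
    """
    if isinstance(rules, str):
        rules = get_enzyme(rules)
    seq = _check_sequence(sequence)
    sites = []
    for i in range(1, len(seq) - 1):
        if any(r.matches(seq[i], seq[i + 1]) for r in rules.rules):
            sites.append(i)
    return sites


def degradable(
    sequence: str, enzyme_panel=AF_PANEL
) -> tuple[bool, dict[str, int]]:
    """Whether any enzyme of the panel cleaves the peptide internally.

    Returns ``(is_degradable, {enzyme_name: n_sites})``.
    """
    panel = list(enzyme_panel)
    if not panel:
        raise UsageError("enzyme panel must not be empty")
    counts = {}
    for enz in panel:
        rs = get_enzyme(enz) if isinstance(enz, str) else enz
        counts[rs.name] = len(cleavage_sites(sequence, rs))
    return any(n > 0 for n in counts.values()), counts


def digest_table(sequences: dict[str, str], enzyme_panel=AF_PANEL):
    """Digest many sequences; returns tidy rows (id, enzyme, n_sites, degradable)."""
    import pandas as pd

    rows = []
    for sid, seq in sequences.items():
        deg, counts = degradable(seq, enzyme_panel)
        for enz, n in counts.items():
            rows.append({"id": sid, "enzyme": enz, "n_sites": n, "degradable": deg})
    return pd.DataFrame(rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Peptide sequences from a FASTA file, keyed by record ID."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such FASTA file: {path}")
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_rules(path: str | Path) -> dict[str, CleavageRuleSet]:
    """Load enzyme rule sets from a YAML file.

    Format::

        enzymes:
          my_enzyme:
            rules:
              - p1: "KR"
                blocked_p1_prime: "P"
              - p1_prime: "FL"
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "enzymes" not in doc:
        raise DataError(f"{path}: rules file must contain an 'enzymes' mapping")
    out = {}
    for name, spec in doc["enzymes"].items():
        rules = tuple(
            _rs(
                p1=r.get("p1"),
                p1_prime=r.get("p1_prime"),
                blocked=r.get("blocked_p1_prime", ()),
            )
            for r in spec.get("rules", [])
        )
        out[name] = CleavageRuleSet(str(name), rules)
    return out
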