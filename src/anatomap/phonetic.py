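"""Double Metaphone phonetic encoding.

The encoder maps an English-ish word to a (primary, alternate) pair of sound
codes; two words are considered phonetically equal when either code coincides.
This is the primitive behind curator-driven approximate matching of annotation
terms against ontology labels: "kidney" and "kiddney" share a primary code,
so a misheard or mistyped annotation can still surface the right class as a
proposal.

The implementation follows Lawrence Philips' published Double Metaphone rules
(initial silent clusters, context-dependent C/G/H handling, the Slavo-Germanic
heuristic, vowels encoded only word-initially, voiced/unvoiced mergers such as
V→F and Z→S). Codes are not truncated to four characters: anatomical
vocabulary is long and polysyllabic, and truncation merges far too many
distinct organ names into one bucket.

Multi-word strings are encoded word by word and the per-word codes joined with
``"-"``; encoding a whole phrase as one pseudo-word discards word boundaries
and inflates false positives.
"""

from __future__ import annotations

import unicodedata

__all__ = ["double_metaphone", "encode_phrase"]

_VOWELS = frozenset("AEIOUY")


def _fold_ascii(text: str) -> str:
    """Strip diacritics and drop non-ASCII leftovers."""
    norm = unicodedata.normalize("NFKD", text)
    return "".join(c for c in norm if ord(c) < 128)


def _slavo_germanic(word: str) -> bool:
    return "W" in word or "K" in word or "CZ" in word or "WITZ" in word


def double_metaphone(word: str) -> tuple[str, str]:
    """Return the (primary, alternate) Double Metaphone codes of *word*.

    The empty string encodes to ``("", "")``. When the alternate code would
    equal the primary it is returned equal (callers may compare either).
    Input is diacritic-folded to ASCII before encoding.
    """
    word = _fold_ascii(word).upper()
    word = "".join(c for c in word if c.isalpha())
    if not word:
        return ("", "")

    length = len(word)
    last = length - 1
    padded = word + "     "
    sg = _slavo_germanic(word)

    pri: list[str] = []
    alt: list[str] = []

    def add(p: str, a: str | None = None) -> None:
        pri.append(p)
        alt.append(p if a is None else a)

    def at(i: int) -> str:
        return padded[i] if i >= 0 else ""

    def seq(i: int, n: int) -> str:
        return padded[i : i + n] if i >= 0 else ""

    def contains(start: int, n: int, *options: str) -> bool:
        return seq(start, n) in options

    pos = 0
    # silent initial clusters: GN-, KN-, PN-, WR-, PS-
    if seq(0, 2) in ("GN", "KN", "PN", "WR", "PS"):
        pos = 1
    if word[0] == "X":  # e.g. Xiphoid — initial X sounds like S
        add("S")
        pos = 1

    while pos < length:
        c = word[pos]

        if c in _VOWELS:
            if pos == 0:
                add("A")
            pos += 1
            continue

        if c == "B":
            add("P")
            pos += 2 if at(pos + 1) == "B" else 1
            continue

        if c == "\xc7":
            add("S")
            pos += 1
            continue

        if c == "C":
            # various germanic: e.g. "ACH" not preceded by vowel
            if (
                pos > 1
                and at(pos - 2) not in _VOWELS
                and contains(pos - 1, 3, "ACH")
                and at(pos + 2) != "I"
                and (at(pos + 2) != "E" or contains(pos - 2, 6, "BACHER", "MACHER"))
            ):
                add("K")
                pos += 2
                continue
            if pos == 0 and contains(pos, 6, "CAESAR"):
                add("S")
                pos += 2
                continue
            if contains(pos, 4, "CHIA"):
                add("K")
                pos += 2
                continue
            if contains(pos, 2, "CH"):
                if pos > 0 and contains(pos, 4, "CHAE"):
                    add("K", "X")
                    pos += 2
                    continue
                if (
                    pos == 0
                    and (contains(pos + 1, 5, "HARAC", "HARIS") or contains(pos + 1, 3, "HOR", "HYM", "HIA", "HEM"))
                    and not contains(0, 5, "CHORE")
                ):
                    add("K")
                    pos += 2
                    continue
                if (
                    contains(0, 4, "VAN ", "VON ")
                    or contains(0, 3, "SCH")
                    or contains(pos - 2, 6, "ORCHES", "ARCHIT", "ORCHID")
                    or contains(pos + 2, 1, "T", "S")
                    or (
                        (contains(pos - 1, 1, "A", "O", "U", "E") or pos == 0)
                        and contains(pos + 2, 1, "L", "R", "N", "M", "B", "H", "F", "V", "W", " ")
                    )
                ):
                    add("K")
                else:
                    if pos > 0:
                        if contains(0, 2, "MC"):
                            add("K")
                        else:
                            add("X", "K")
                    else:
                        add("X")
                pos += 2
                continue
            if contains(pos, 2, "CZ") and not contains(pos - 2, 4, "WICZ"):
                add("S", "X")
                pos += 2
                continue
            if contains(pos + 1, 3, "CIA"):
                add("X")
                pos += 3
                continue
            if contains(pos, 2, "CC") and not (pos == 1 and word[0] == "M"):
                if contains(pos + 2, 1, "I", "E", "H") and not contains(pos + 2, 2, "HU"):
                    if (pos == 1 and at(pos - 1) == "A") or contains(pos - 1, 5, "UCCEE", "UCCES"):
                        add("KS")
                    else:
                        add("X")
                    pos += 3
                    continue
                add("K")
                pos += 2
                continue
            if contains(pos, 2, "CK", "CG", "CQ"):
                add("K")
                pos += 2
                continue
            if contains(pos, 2, "CI", "CE", "CY"):
                if contains(pos, 3, "CIO", "CIE", "CIA"):
                    add("S", "X")
                else:
                    add("S")
                pos += 2
                continue
            add("K")
            if contains(pos + 1, 2, " C", " Q", " G"):
                pos += 3
            elif contains(pos + 1, 1, "C", "K", "Q") and not contains(pos + 1, 2, "CE", "CI"):
                pos += 2
            else:
                pos += 1
            continue

        if c == "D":
            if contains(pos, 2, "DG"):
                if contains(pos + 2, 1, "I", "E", "Y"):
                    add("J")  # e.g. "ridge"
                    pos += 3
                else:
                    add("TK")
                    pos += 2
                continue
            if contains(pos, 2, "DT", "DD"):
                add("T")
                pos += 2
                continue
            add("T")
            pos += 1
            continue

        if c == "F":
            add("F")
            pos += 2 if at(pos + 1) == "F" else 1
            continue

        if c == "G":
            if at(pos + 1) == "H":
                if pos > 0 and at(pos - 1) not in _VOWELS:
                    add("K")
                    pos += 2
                    continue
                if pos == 0:
                    if at(pos + 2) == "I":
                        add("J")
                    else:
                        add("K")
                    pos += 2
                    continue
                if (
                    (pos > 1 and contains(pos - 2, 1, "B", "H", "D"))
                    or (pos > 2 and contains(pos - 3, 1, "B", "H", "D"))
                    or (pos > 3 and contains(pos - 4, 1, "B", "H"))
                ):
                    pos += 2
                    continue
                if pos > 2 and at(pos - 1) == "U" and contains(pos - 3, 1, "C", "G", "L", "R", "T"):
                    add("F")  # e.g. "laugh", "cough"
                elif pos > 0 and at(pos - 1) != "I":
                    add("K")
                pos += 2
                continue
            if at(pos + 1) == "N":
                if pos == 1 and word[0] in _VOWELS and not sg:
                    add("KN", "N")
                elif not contains(pos + 2, 2, "EY") and at(pos + 1) != "Y" and not sg:
                    add("N", "KN")
                else:
                    add("KN")
                pos += 2
                continue
            if contains(pos + 1, 2, "LI") and not sg:
                add("KL", "L")
                pos += 2
                continue
            if pos == 0 and (at(pos + 1) == "Y" or contains(pos + 1, 2, "ES", "EP", "EB", "EL", "EY", "IB", "IL", "IN", "IE", "EI", "ER")):
                add("K", "J")
                pos += 2
                continue
            if (contains(pos + 1, 2, "ER") or at(pos + 1) == "Y") and not contains(0, 6, "DANGER", "RANGER", "MANGER") and not contains(pos - 1, 1, "E", "I") and not contains(pos - 1, 3, "RGY", "OGY"):
                add("K", "J")
                pos += 2
                continue
            if contains(pos + 1, 1, "E", "I", "Y") or contains(pos - 1, 4, "AGGI", "OGGI"):
                if contains(0, 4, "VAN ", "VON ") or contains(0, 3, "SCH") or contains(pos + 1, 2, "ET"):
                    add("K")
                elif contains(pos + 1, 4, "IER "):
                    add("J")
                else:
                    add("J", "K")
                pos += 2
                continue
            add("K")
            pos += 2 if at(pos + 1) == "G" else 1
            continue

        if c == "H":
            # keep only between vowels or word-initial before a vowel
            if (pos == 0 or at(pos - 1) in _VOWELS) and at(pos + 1) in _VOWELS:
                add("H")
                pos += 2
            else:
                pos += 1
            continue

        if c == "J":
            if contains(pos, 4, "JOSE") or contains(0, 4, "SAN "):
                if (pos == 0 and at(pos + 4) == " ") or contains(0, 4, "SAN "):
                    add("H")
                else:
                    add("J", "H")
                pos += 1
                continue
            if pos == 0 and not contains(pos, 4, "JOSE"):
                add("J", "A")
            elif at(pos - 1) in _VOWELS and not sg and (at(pos + 1) == "A" or at(pos + 1) == "O"):
                add("J", "H")
            elif pos == last:
                add("J", "")
            elif not contains(pos + 1, 1, "L", "T", "K", "S", "N", "M", "B", "Z") and not contains(pos - 1, 1, "S", "K", "L"):
                add("J")
            pos += 2 if at(pos + 1) == "J" else 1
            continue

        if c == "K":
            add("K")
            pos += 2 if at(pos + 1) == "K" else 1
            continue

        if c == "L":
            if at(pos + 1) == "L":
                if (
                    pos == length - 3
                    and contains(pos - 1, 4, "ILLO", "ILLA", "ALLE")
                ) or (
                    (contains(last - 1, 2, "AS", "OS") or contains(last, 1, "A", "O"))
                    and contains(pos - 1, 4, "ALLE")
                ):
                    add("L", "")
                    pos += 2
                    continue
                pos += 2
            else:
                pos += 1
            add("L")
            continue

        if c == "M":
            add("M")
            if (contains(pos - 1, 3, "UMB") and (pos + 1 == last or contains(pos + 2, 2, "ER"))) or at(pos + 1) == "M":
                pos += 2
            else:
                pos += 1
            continue

        if c == "N":
            add("N")
            pos += 2 if at(pos + 1) == "N" else 1
            continue

        if c == "\xd1":
            add("N")
            pos += 1
            continue

        if c == "P":
            if at(pos + 1) == "H":
                add("F")
                pos += 2
                continue
            add("P")
            pos += 2 if contains(pos + 1, 1, "P", "B") else 1
            continue

        if c == "Q":
            add("K")
            pos += 2 if at(pos + 1) == "Q" else 1
            continue

        if c == "R":
            if pos == last and not sg and contains(pos - 2, 2, "IE") and not contains(pos - 4, 2, "ME", "MA"):
                add("", "R")
            else:
                add("R")
            pos += 2 if at(pos + 1) == "R" else 1
            continue

        if c == "S":
            if contains(pos - 1, 3, "ISL", "YSL"):  # silent: "island"
                pos += 1
                continue
            if pos == 0 and contains(pos, 5, "SUGAR"):
                add("X", "S")
                pos += 1
                continue
            if contains(pos, 2, "SH"):
                if contains(pos + 1, 4, "HEIM", "HOEK", "HOLM", "HOLZ"):
                    add("S")
                else:
                    add("X")
                pos += 2
                continue
            if contains(pos, 3, "SIO", "SIA") or contains(pos, 4, "SIAN"):
                if sg:
                    add("S")
                else:
                    add("S", "X")
                pos += 3
                continue
            if (pos == 0 and contains(pos + 1, 1, "M", "N", "L", "W")) or contains(pos + 1, 1, "Z"):
                add("S", "X")
                pos += 2 if contains(pos + 1, 1, "Z") else 1
                continue
            if contains(pos, 2, "SC"):
                if at(pos + 2) == "H":
                    if contains(pos + 3, 2, "OO", "ER", "EN", "UY", "ED", "EM"):
                        if contains(pos + 3, 2, "ER", "EN"):
                            add("X", "SK")
                        else:
                            add("SK")
                    else:
                        if pos == 0 and word[3] not in _VOWELS and word[3] != "W":
                            add("X", "S")
                        else:
                            add("X")
                elif contains(pos + 2, 1, "I", "E", "Y"):
                    add("S")
                else:
                    add("SK")
                pos += 3
                continue
            if pos == last and contains(pos - 2, 2, "AI", "OI"):
                add("", "S")  # french e.g. "resnais"
            else:
                add("S")
            pos += 2 if contains(pos + 1, 1, "S", "Z") else 1
            continue

        if c == "T":
            if contains(pos, 4, "TION") or contains(pos, 3, "TIA", "TCH"):
                add("X")
                pos += 3
                continue
            if contains(pos, 2, "TH") or contains(pos, 3, "TTH"):
                if contains(pos + 2, 2, "OM", "AM") or contains(0, 4, "VAN ", "VON ") or contains(0, 3, "SCH"):
                    add("T")
                else:
                    add("0", "T")
                pos += 2
                continue
            add("T")
            pos += 2 if contains(pos + 1, 1, "T", "D") else 1
            continue

        if c == "V":
            add("F")
            pos += 2 if at(pos + 1) == "V" else 1
            continue

        if c == "W":
            if contains(pos, 2, "WR"):
                add("R")
                pos += 2
                continue
            if pos == 0 and (at(pos + 1) in _VOWELS or contains(pos, 2, "WH")):
                if at(pos + 1) in _VOWELS:
                    add("A", "F")
                else:
                    add("A")
            if (pos == last and at(pos - 1) in _VOWELS) or contains(pos - 1, 5, "EWSKI", "EWSKY", "OWSKI", "OWSKY") or contains(0, 3, "SCH"):
                add("", "F")
                pos += 1
                continue
            if contains(pos, 4, "WICZ", "WITZ"):
                add("TS", "FX")
                pos += 4
                continue
            pos += 1
            continue

        if c == "X":
            if not (pos == last and (contains(pos - 3, 3, "IAU", "EAU") or contains(pos - 2, 2, "AU", "OU"))):
                add("KS")
            pos += 2 if contains(pos + 1, 1, "C", "X") else 1
            continue

        if c == "Z":
            if at(pos + 1) == "H":
                add("J")
                pos += 2
                continue
            if contains(pos + 1, 2, "ZO", "ZI", "ZA") or (sg and pos > 0 and at(pos - 1) != "T"):
                add("S", "TS")
            else:
                add("S")
            pos += 2 if at(pos + 1) == "Z" else 1
            continue

        pos += 1

    primary = "".join(pri)
    alternate = "".join(alt)
    return (primary, alternate)


def encode_phrase(text: str, sep: str = "-") -> tuple[str, str]:
    """Encode a multi-word string word by word, joining codes with *sep*.

    Returns ``("", "")`` for empty or all-whitespace input. Word order is
    preserved, so "bone marrow" and "marrow bone" encode differently.
    """
    words = text.split()
    if not words:
        return ("", "")
    prims, alts = zip(*(double_metaphone(w) for w in words))
    return (sep.join(prims), sep.join(alts))
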