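"""Exception types shared across the package."""


class InputError(ValueError):
    """Malformed or inconsistent user input (unknown locus, bad allele symbol, ...)."""


class ParseError(InputError):
    """A table file violated the expected dialect; message names the offending row."""


class UndefinedStatisticError(ValueError):
    """A statistic has no defined value for the given counts (e.g. n = 0)."""


class DegenerateTableError(ValueError):
    """A contingency table collapsed to fewer than two informative categories."""
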