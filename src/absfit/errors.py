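"""Exception hierarchy shared across the package."""


class AbsfitError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(AbsfitError):
    """A character outside the strict {A, C, G, T} alphabet was encountered."""

    def __init__(self, taxon: str, column: int, char: str):
        self.taxon = taxon
        self.column = column
        self.char = char
        super().__init__(
            f"forbidden character {char!r} in sequence {taxon!r} at column {column} "
            "(alignments must be gap-free and contain only A/C/G/T)"
        )


class DimensionError(AbsfitError):
    """Alignment rows have unequal lengths or the matrix is degenerate."""


class DuplicateTaxonError(AbsfitError):
    """Two sequences share the same taxon label."""


class UnresolvedTreeError(AbsfitError):
    """A candidate tree contains a polytomy; the test needs fully resolved trees."""


class TaxonMismatchError(AbsfitError):
    """Tree leaf set and alignment taxon set (or two trees) disagree."""


class SubsetSizeError(AbsfitError):
    """A node-specific taxon subset (or its complement) has fewer than 2 members."""


class ApplicabilityError(AbsfitError):
    """The Gelfand-Ghosh applicability conditions fail: one of the 10 pair
    categories is absent from the observed alignment or from the whole
    replicate distribution."""


class OrderMismatchError(AbsfitError):
    """Two D-value profiles were computed over different subset orders."""


class ZeroVarianceError(AbsfitError):
    """A replicate delta distribution has zero spread; no Z-score is defined."""
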