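"""Exception hierarchy for the toolkit.

Every error raised by circkit derives from :class:`CircKitError`, so callers
can catch one type at the CLI boundary.
"""


class CircKitError(Exception):
    """Base class for all circkit errors."""


# --- io_formats -------------------------------------------------------------

class MalformedFasta(CircKitError):
    """FASTA syntax violation (e.g. sequence data before any header)."""


class EmptySequence(CircKitError):
    """A record with a zero-length sequence."""


class OrphanExon(CircKitError):
    """An exon/CDS feature with no parent transcript attribute."""


class CoordinateError(CircKitError):
    """Inconsistent coordinates (end < start, CDS length not a codon multiple)."""


class BlockSumMismatch(CircKitError):
    """BED12 blocks extend beyond the row's interval."""


class StrandMissing(CircKitError):
    """A record that requires a strand does not carry one."""


class MissingHeader(CircKitError):
    """SAM file without a header."""


class InconsistentHitCount(CircKitError):
    """Hit-count tag disagrees with the number of records for a read (strict mode)."""


# --- circ_model -------------------------------------------------------------

class ZeroLibrary(CircKitError):
    """Mapped-read total of zero; RPM undefined."""


class ConstantVector(CircKitError):
    """Pearson correlation undefined for a constant vector."""


class StrandMismatch(CircKitError):
    """circRNAs grouped on one gene disagree in strand."""


class BoundaryMismatch(CircKitError):
    """Isoform chains compared for internal AS do not share outer boundaries."""


# --- degradome --------------------------------------------------------------

class PositionOutOfRange(CircKitError):
    """A 5' end falls outside the declared reference length."""


class InvalidParameters(CircKitError):
    """Binomial test parameters outside their domain."""


class EmptyPileup(CircKitError):
    """Peak calling requested on a pileup with no weight."""


class ChromMismatch(CircKitError):
    """Peak and circRNA live on different chromosomes."""


class SequenceUnavailable(CircKitError):
    """An exon chain cannot be resolved against the supplied genome."""


class ReadTooShort(CircKitError):
    """Read shorter than twice the junction overhang requirement."""


# --- mirna_targeting --------------------------------------------------------

class SiteOutOfRange(CircKitError):
    """Cleavage-context site outside the transcript."""


class WindowTooShort(CircKitError):
    """Target window too short to host a duplex."""


class Position10Unpaired(CircKitError):
    """miRNA position 10 is not paired; no slice site can be predicted."""


class LengthOutOfRange(CircKitError):
    """Small-RNA read outside the 18-26 nt range."""


# --- circ_orf ---------------------------------------------------------------

class CircleTooShort(CircKitError):
    """Circle shorter than one codon."""


class InvalidCDS(CircKitError):
    """CDS coordinates outside the transcript or not a codon multiple."""


# --- enrichment_perm --------------------------------------------------------

class UniverseExhausted(CircKitError):
    """Could not place a random segment after bounded retries."""


# --- synthetic_fixtures -----------------------------------------------------

class ConfigInvalid(CircKitError):
    """Simulation configuration violates its invariants."""
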