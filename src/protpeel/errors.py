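"""Exception hierarchy shared across the package."""


class ProtPeelError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(ProtPeelError):
    """The input coordinate file could not be parsed as PDB."""


class ChainNotFoundError(ProtPeelError):
    """The requested chain is absent from the selected model."""

    def __init__(self, chain: str, available: list[str]):
        self.chain = chain
        self.available = list(available)
        super().__init__(
            f"chain {chain!r} not found; available chains: {self.available}"
        )


class EmptyStructureError(ProtPeelError):
    """No standard residue with a C-alpha atom survived cleaning."""


class DegenerateDistributionError(ProtPeelError):
    """Decoy energies have zero spread; a Z-score is undefined."""


class FixtureError(ProtPeelError):
    """A synthetic-structure request is geometrically infeasible."""
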