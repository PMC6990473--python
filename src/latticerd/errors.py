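"""Exception hierarchy for latticerd."""


class LatticeRDError(Exception):
    """Base class for all latticerd errors."""


class CoordinateError(LatticeRDError):
    """A voxel coordinate lies outside the lattice."""


class ConfigurationError(LatticeRDError):
    """A model or domain-decomposition configuration is invalid."""


class ValidationError(ConfigurationError):
    """A model file failed schema validation; carries the itemized problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("model validation failed:\n" + "\n".join(f"- {p}" for p in self.problems))


class ImmobileSpeciesError(LatticeRDError):
    """A diffusion quantity was requested for a species with D = 0."""


class InfeasibleRateError(LatticeRDError):
    """An effective bimolecular rate meets or exceeds the diffusion-limited rate."""


class CommunicationError(LatticeRDError):
    """Inter-worker transport failure; message names rank, stage and direction."""


class GatherError(LatticeRDError):
    """Per-rank logger files are missing or inconsistent."""


class AnalysisError(LatticeRDError):
    """An analysis routine received unusable input (e.g. a single time point)."""
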