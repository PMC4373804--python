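"""hapcol: haplotype networks and inter-island colonization metrics.

Workflow: read or simulate an aligned mitochondrial dataset, collapse it
into a haplotype x island table, build the parsimony haplotype network,
rank haplotypes by coalescent ancestrality criteria, and compute the
colonization metrics (chorological minimum, maximum potential events,
inferred events under three haplotype-sharing rules, colonization
success).
"""

__version__ = "0.1.0"

from .errors import (AlignmentError, EmptyResultError, HapcolError,
                     InputError, UndefinedRatioError,
                     UnsupportedOperationError)
from .haplotypes import (Alignment, Haplotype, HaplotypeTable,
                         collapse_haplotypes, read_alignment, read_incidence,
                         read_metadata, trim_alignment, write_alignment)
from .metrics import (ColonizationRecord, MetricsResult, SuccessRatio,
                      chorological_minimum, colonization_success,
                      compute_metrics, inferred_events, inferred_events_all,
                      max_potential, read_species_table, species_report)
from .network import (AncestralityReport, Connection, HaplotypeNetwork,
                      ancestrality_rank, build_network, classify_nodes,
                      lineages, pairwise_distances, write_edgelist,
                      write_graphml)
from .pipeline import PipelineConfig, run_pipeline
from .simulate import (GenealogyEntry, MigrationEvent, SimulatedDataset,
                       SimulationParams, galapagos_like,
                       recovery_experiment, simulate_colonization,
                       true_event_count)


def fixture_path(name: str):
    """Path to one of the packaged reference data files."""
    from importlib.resources import files

    return files("hapcol.data").joinpath(name)
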