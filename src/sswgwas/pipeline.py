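"""End-to-end orchestration: QC -> H-inverse -> AI-REML -> weighted ssGWAS."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import RunConfig
from .genotypes import (GenotypeMatrix, QcReport, allele_frequencies,
                        center_matrix, run_qc)
from .kinship import MarkerWeights, blend, g_matrix, h_inverse
from .mme import (DesignMatrices, ModelSpec, PhenotypeTable,
                  VarianceComponents, build_design, prepare_phenotypes,
                  reml_aireml)
from .pedigree import Pedigree, a_inverse, a_submatrix, inbreeding
from .wssgwas import (IterationResult, RegionSet, run_weighted_iterations,
                      select_regions)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    qc_reports: list[QcReport]
    genotypes: GenotypeMatrix
    design: DesignMatrices
    vc: VarianceComponents
    iterations: list[IterationResult]
    regions: RegionSet
    genotyped_index: np.ndarray
    weights_final: MarkerWeights = field(init=False)

    def __post_init__(self) -> None:
        self.weights_final = self.iterations[-1].weights

    @property
    def final(self) -> IterationResult:
        return self.iterations[-1]


def run_pipeline(
    ped: Pedigree,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    model: ModelSpec,
    config: RunConfig,
    *,
    skip_qc: bool = False,
) -> PipelineResult:
    """Run the full weighted single-step GWAS on in-memory inputs."""
    if skip_qc:
        g, reports = genotypes, []
    else:
        g, reports = run_qc(genotypes, ped, config)

    ph = prepare_phenotypes(phenotypes, model, config.outlier_sd,
                            config.trait_floors)
    des = build_design(ph, model, ped)

    freqs = allele_frequencies(g)
    Z = center_matrix(g, freqs)
    genotyped_index = np.array([ped.code(a) for a in g.animal_ids],
                               dtype=np.int64)
    F = inbreeding(ped)
    Ainv = a_inverse(ped, F)
    A22 = a_submatrix(ped, genotyped_index)

    w0 = MarkerWeights.uniform(g.n_snps)
    G = g_matrix(Z, w0, freqs)
    Gstar = blend(G, A22, config.alpha_blend)
    hinv = h_inverse(Ainv, A22, Gstar, genotyped_index, config.alpha_blend)

    vc = reml_aireml(des.y, des.X, des.record_animals, hinv)
    log.info("AI-REML: s2u=%.4g s2e=%.4g h2=%.3f (converged=%s, %d it)",
             vc.sigma2_u, vc.sigma2_e, vc.h2, vc.converged, vc.n_iter)

    iterations = run_weighted_iterations(
        des.y, des.X, des.record_animals, Ainv, A22, genotyped_index,
        Z, freqs, g.snp_map, vc,
        alpha=config.alpha_blend,
        window_size=config.window_size,
        n_iterations=config.n_weight_iterations,
        start_weights=w0,
    )
    regions = select_regions(iterations[-1].windows, config.region_threshold_pct)
    return PipelineResult(
        qc_reports=reports, genotypes=g, design=des, vc=vc,
        iterations=iterations, regions=regions,
        genotyped_index=genotyped_index,
    )
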