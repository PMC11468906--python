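"""End-to-end orchestration: simulate -> peptides -> rank -> assemble ->
design -> formulate, with a manifest capturing every parameter of the run.

``run_design`` is deterministic: identical config and seed give
byte-identical outputs.  Every output file carries a header naming the
package version and the manifest's config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .binding import ToyPWMPredictor
from .codondesign import (
    DEFAULT_EXACT_LIMIT_NT,
    DEFAULT_WINDOW_CODONS,
    DEFAULT_WINDOW_STRIDE,
    EnergyModel,
    design,
)
from .construct import ConstructSpec, assemble_construct, export, naive_codon_source
from .io import (
    builtin_codon_usage,
    write_cds_fasta,
    write_expression_table,
    write_hla_alleles,
    write_variant_table,
)
from .peptides import extract_candidates, peptide_table, write_peptide_fastas
from .quant import FormulationConfig, example_formulation_config, lpp_recipe
from .ranking import (
    DEFAULT_TOP_N,
    FeatureVector,
    RankInput,
    ScoreWeights,
    ranked_table,
    rank_and_select,
    scan_subpeptides,
)
from .simulate import CohortParams, generate_cohort


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of a pipeline run; serializable to YAML."""

    seed: int = 0
    n_transcripts: int = 40
    n_variants: int = 60
    top_n: int = DEFAULT_TOP_N
    cohort: CohortParams = field(default_factory=CohortParams)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    construct: ConstructSpec = field(default_factory=ConstructSpec)
    energy: EnergyModel = field(default_factory=EnergyModel)
    lam: float = 1.0
    codon_source: str = "naive"  # "naive" | "optimize"
    exact_limit_nt: int = DEFAULT_EXACT_LIMIT_NT
    window_codons: int = DEFAULT_WINDOW_CODONS
    window_stride: int = DEFAULT_WINDOW_STRIDE
    formulation_mrna_ug: float = 100.0
    formulation: FormulationConfig = field(
        default_factory=example_formulation_config
    )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["cohort"]["hla_alleles"] = list(self.cohort.hla_alleles)
        d["formulation"]["mole_fractions"] = dict(self.formulation.mole_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            for k in ("cds_len_codons", "hla_alleles"):
                if k in c:
                    c[k] = tuple(c[k])
            d["cohort"] = CohortParams(**c)
        if "weights" in d:
            d["weights"] = ScoreWeights(**d["weights"])
        if "construct" in d:
            d["construct"] = ConstructSpec(**d["construct"])
        if "energy" in d:
            d["energy"] = EnergyModel(**d["energy"])
        if "formulation" in d:
            d["formulation"] = FormulationConfig(**d["formulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# neovax {__version__} config_hash={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def run_design(config: RunConfig, out_dir: str | Path) -> Path:
    """Run the in-silico pipeline end to end into ``out_dir``.

    Emits the simulated cohort, peptide windows, ranked candidates with the
    filter-attrition log, the assembled construct (FASTA, GenBank-style,
    region TSV), design metrics, the formulation recipe, and a manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config

    # 1. simulate
    cohort = generate_cohort(cfg.seed, cfg.n_transcripts, cfg.n_variants, cfg.cohort)
    write_cds_fasta(cohort.transcripts, out / "cds.fasta")
    write_variant_table(cohort.variants, out / "variants.tsv")
    write_expression_table(cohort.expression, out / "expression.tsv")
    write_hla_alleles(cohort.hla_alleles, out / "hla.txt")

    # 2. peptides
    candidates, skipped = extract_candidates(cohort.transcripts, cohort.variants)
    _write_tsv(peptide_table(candidates), out / "peptides.tsv", cfg)
    write_peptide_fastas(candidates, out / "peptides_mut.fasta", out / "peptides_wt.fasta")

    # 3. features + rank
    tpm_by_transcript = dict(
        zip(cohort.expression["transcript_id"], cohort.expression["tpm"])
    )
    predictor = ToyPWMPredictor(cohort.hla_alleles, seed=cfg.seed)
    rank_inputs = []
    for c in candidates:
        summary = scan_subpeptides(c.pair, cohort.hla_alleles, predictor)
        fv = FeatureVector(
            vaf_tumor_dna=c.variant.vaf_tumor_dna,
            vaf_normal_dna=c.variant.vaf_normal_dna,
            vaf_tumor_rna=c.variant.vaf_tumor_rna,
            expr_tpm=tpm_by_transcript[c.variant.transcript_id],
            best_mut_affinity_nM=summary.best_mut_affinity_nM,
            best_wt_affinity_nM=summary.best_wt_affinity_nM,
        )
        rank_inputs.append(RankInput(c.candidate_id, c.pair, fv))
    selected, attrition = rank_and_select(rank_inputs, cfg.weights, cfg.top_n)
    _write_tsv(ranked_table(selected, attrition), out / "ranked.tsv", cfg)

    # 4. assemble + 5. design
    design_note: dict[str, str] = {}
    if selected:
        if cfg.codon_source == "optimize":
            def codon_source(aa: str) -> str:
                res = design(
                    aa,
                    usage=builtin_codon_usage(),
                    model=cfg.energy,
                    lam=cfg.lam,
                    exact_limit_nt=cfg.exact_limit_nt,
                    window_codons=cfg.window_codons,
                    window_stride=cfg.window_stride,
                )
                design_note["mode"] = res.mode
                design_note["mfe_proxy"] = f"{res.mfe_proxy:g}"
                design_note["cai"] = f"{res.cai:.6f}"
                design_note["objective"] = f"{res.objective:g}"
                design_note["lambda"] = f"{cfg.lam:g}"
                return res.rna_codons
        elif cfg.codon_source == "naive":
            codon_source = naive_codon_source(builtin_codon_usage())
        else:
            raise ValueError(f"unknown codon_source {cfg.codon_source!r}")
        construct = assemble_construct(
            peptides=[c.pair.mut_peptide for c in selected],
            peptide_ids=[c.candidate_id for c in selected],
            spec=cfg.construct,
            codon_source=codon_source,
            extra_notes={"codon_source": cfg.codon_source},
        )
        export(construct, out / "construct.fasta", "fasta")
        export(construct, out / "construct.gb", "genbank")
        export(construct, out / "construct_regions.tsv", "tsv")
        with open(out / "design_metrics.json", "w") as fh:
            json.dump(
                {"codon_source": cfg.codon_source, **design_note},
                fh,
                indent=2,
                sort_keys=True,
            )

    # 6. formulate
    recipe = lpp_recipe(cfg.formulation_mrna_ug, cfg.formulation)
    recipe_out = {
        "mrna_mass_ug": recipe.mrna_mass_ug,
        "phosphate_umol": recipe.phosphate_umol,
        "component_umol": recipe.component_umol,
        "component_masses_ug": recipe.component_masses_ug,
        "mrna_volume_ul": recipe.mrna_volume_ul,
        "protamine_volume_ul": recipe.protamine_volume_ul,
        "ethanol_volume_ul": recipe.ethanol_volume_ul,
        "np_ratio_recomputed": recipe.recomputed_np_ratio(),
        "mole_percent_recomputed": recipe.recomputed_mole_fractions(),
    }
    with open(out / "recipe.yaml", "w") as fh:
        fh.write(_header(cfg))
        yaml.safe_dump(recipe_out, fh, sort_keys=True)

    # manifest
    manifest = {
        "package": "neovax",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "n_candidates": len(candidates),
        "n_skipped_variants": len(skipped),
        "n_selected": len(selected),
        "selected_ids": [c.candidate_id for c in selected],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
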