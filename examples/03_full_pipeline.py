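"""The full detection pipeline on a small synthetic proteome.

Generates a reduced synthetic study (fewer proteins than the default test
conditions, for speed), runs every protein through search, fold recognition
and cross-species validation, and prints the per-call tier decisions plus
the proteome summary.
"""

from remotethread import run_proteome
from remotethread.fixtures import FixtureSpec, generate_bundle
from remotethread.pipeline import PipelineConfig, PipelineResources, Tier

spec = FixtureSpec(
    seed=0,
    n_significant_proteins=6,
    n_remote_proteins=3,
    n_remote_with_orthologs=2,
    n_decoy_proteins=8,
)
print("generating synthetic study (profiles, structures, proteome, orthologs)...")
bundle = generate_bundle(spec)

resources = PipelineResources(
    profiles=bundle.profiles,
    library=bundle.library,
    structure_map=bundle.structure_map,
    cdf=bundle.cdf,
    orthologs=bundle.ortholog_table,
    ortholog_sequences=bundle.ortholog_sequences,
    essentials=bundle.essentials,
)
calls, summary = run_proteome(bundle.proteome, resources, PipelineConfig())

print(f"\n{'protein':>8} {'profile':>8} {'E-value':>10} {'tier':>20} {'level':>6}")
for c in calls:
    if c.tier is Tier.REJECTED:
        continue
    level = c.validation.level if c.validation else "-"
    print(f"{c.hit.protein_id:>8} {c.hit.profile_accession:>8} "
          f"{c.hit.evalue:>10.3g} {c.tier.value:>20} {level:>6}")

print("\nsummary:")
for key, value in summary.as_dict().items():
    print(f"  {key}: {value}")

print(
    "\nsig* proteins carry zero-divergence domains (tier significant, no "
    "threading);\nrem* proteins carry engineered remote members (E > 0.1) "
    "whose folds were\nconfirmed; those with ortholog trios validate at "
    "level >= 2.  Decoy junk hits\nare threaded and rejected."
)
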