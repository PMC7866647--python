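"""Score one patient: karyotype -> IPSS-R -> mutation points -> MIPSS-R."""

from mipssr import (
    ClinicalComponents,
    classify_cytogenetics,
    ipssr_total,
    mipssr_score,
    mutation_stratum,
    normalize_genes,
    parse_iscn,
)

# a patient with isolated del(5q), moderate cytopenias, TET2+ASXL1 mutated
report = parse_iscn("46,XX,del(5)(q13q33)")
cyto = classify_cytogenetics(report)
print(f"karyotype {report.raw!r}: {report.n_abnormalities} abnormality, "
      f"cytogenetic risk {cyto.level} ({cyto.points} points)")

ipssr = ipssr_total(
    ClinicalComponents(hemoglobin=9.2, platelets=53, anc=1.18, blasts=1, cyto=cyto)
)
print(f"IPSS-R total {ipssr.total} -> {ipssr.category} "
      f"(cyto {ipssr.points_cyto}, blasts {ipssr.points_blasts}, "
      f"hgb {ipssr.points_hgb}, plt {ipssr.points_plt}, anc {ipssr.points_anc})")

profile = normalize_genes("TET2;ASXL1")
mut = mutation_stratum(profile)
print(f"mutations {sorted(profile.genes)} -> {mut.stratum} ({mut.points} points)")

combined = mipssr_score(mut.points, ipssr.total)
print(f"MIPSS-R = 1.047 x {mut.points} + 0.641 x {ipssr.total} "
      f"= {combined.score_display:.2f} -> {combined.category}")
# The combined score moves this IPSS-R 'low' patient according to how many
# mutated genes she carries: two genes add 2 x 1.047 to the log hazard scale.
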