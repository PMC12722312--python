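feature,category
pct_reads_inverted,structural
inversion_size,structural
pct_reads_duplicated,structural
duplication_size,structural
insert_frequency,structural
homology,context
homology_1_3,context
homology_gt6,context
untemplated,context
blunt_fraction,context
homology_inserts,context
untemplated_inserts,context
homology_score_fw,context
homology_score_rv,context
donor_score_W,context
donor_score_S,context
donor_score_WRCY,context
acceptor_score_W,context
acceptor_score_S,context
acceptor_score_RGYW,context
donor_complexity,context
acceptor_complexity,context
breaks_normalized,breakpoint_matrix
pct_duplications,breakpoint_matrix
pct_inversions,breakpoint_matrix
pct_direct_switch,breakpoint_matrix
pct_sequential_switch,breakpoint_matrix
pct_intraswitch_deletion,breakpoint_matrix
pct_intraswitch_inversion,breakpoint_matrix
pct_intraswitch_duplication,breakpoint_matrix
pct_breaks_SM_SG,breakpoint_matrix
pct_breaks_SM_SA,breakpoint_matrix
pct_breaks_SM_SE,breakpoint_matrix
pct_breaks_SG_SG,breakpoint_matrix
pct_breaks_SG_SA,breakpoint_matrix
pct_breaks_SG_SE,breakpoint_matrix
pct_breaks_SA_SA,breakpoint_matrix
pct_breaks_SA_SE,breakpoint_matrix
break_dispersion_SM,breakpoint_matrix
break_dispersion_SG3,breakpoint_matrix
break_dispersion_SG1,breakpoint_matrix
break_dispersion_SA1,breakpoint_matrix
break_dispersion_SG2,breakpoint_matrix
break_dispersion_SG4,breakpoint_matrix
break_dispersion_SE,breakpoint_matrix
break_dispersion_SA2,breakpoint_matrix
breakpoint_spread,breakpoint_matrix
frag_length_mean,breakpoint_matrix
frag_length_std,breakpoint_matrix
frag_gc,breakpoint_matrix
cluster_size_mean,diversity
cluster_size_std,diversity
clusters,diversity
clusters_eff,diversity
cluster_gini,diversity
cluster_entropy,diversity
cluster_inverse_simpson,diversity
occupancy_top_clone,diversity
occupancy_big_clones,diversity
pct_clusters_SG3,isotype
pct_clusters_SG1,isotype
pct_clusters_SA1,isotype
pct_clusters_SG2,isotype
pct_clusters_SG4,isotype
pct_clusters_SE,isotype
pct_clusters_SA2,isotype
pct_clusters_SG,isotype
pct_clusters_SA,isotype
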