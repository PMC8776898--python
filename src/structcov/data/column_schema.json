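{
  "regional_<contrast>_<measure>.csv": {
    "region_id": "atlas region identifier",
    "contrast": "full | male | female (treated vs control within that subset)",
    "measure": "absolute (mm^3) | relative (fraction of subject TBV)",
    "mean_diff": "treated mean minus control mean, in the measure's units",
    "t": "Welch two-sample t statistic",
    "p": "two-tailed p-value",
    "q": "FDR-adjusted q-value (method recorded in the manifest)",
    "cohens_d": "Cohen's d with pooled SD, signed treated minus control",
    "significant_at_q05": "true when q passes the FDR rejection rule at level 0.05"
  },
  "tbv_comparison.csv": {
    "f_statistic": "one-way ANOVA F across the four sex-by-treatment cells",
    "p_value": "ANOVA p-value",
    "mean_<cell>": "cell mean total brain volume (mm^3)"
  },
  "tbv_pairwise.csv": {
    "cell_a": "first cell of the pair",
    "cell_b": "second cell of the pair",
    "mean_diff": "cell_a mean minus cell_b mean (mm^3)",
    "p_adj": "Tukey-HSD adjusted p-value"
  },
  "area_effects.csv": {
    "area": "anatomical area name from the hierarchy",
    "mean_cohens_d": "unweighted mean Cohen's d over subset regions in the area",
    "n_regions": "number of subset regions contributing"
  },
  "dimorphism.csv": {
    "region_id": "a-priori region tested",
    "control_d": "Cohen's d male minus female within controls",
    "control_p": "Welch p, male vs female within controls",
    "treated_d": "Cohen's d male minus female within treated",
    "treated_p": "Welch p, male vs female within treated",
    "interaction_p": "sex-by-group interaction p from a two-way OLS model",
    "pattern": "dimorphism_lost | dimorphic_preserved | not_dimorphic | other"
  },
  "covariance_blocks.csv": {
    "cluster_a": "first cluster of the unordered pair",
    "cluster_b": "second cluster of the unordered pair",
    "block_n_per_group": "length of each group's block r vector under the convention in force",
    "kw_h": "tie-corrected Kruskal-Wallis H across the four groups",
    "p": "chi-square p on k-1 df",
    "eta_squared": "(H - k + 1) / (n - k), floored at 0",
    "large_effect": "eta_squared strictly greater than 0.14",
    "mean_r_<group>": "arithmetic mean of the group's block r values",
    "q": "FDR-adjusted q across the 21 blocks (two-stage step-up by default)",
    "omnibus_passed": "q rejection and large_effect both true",
    "effect_class": "treatment | sex_within_treated | both | none"
  },
  "covariance_matrix_<group>.csv": {
    "<region_id>": "square Pearson r matrix; first column and header row hold region ids"
  },
  "brain_behavior.csv": {
    "region_id": "region whose volume is correlated",
    "measure": "behavioral measure name",
    "stratum": "sex-by-treatment cell",
    "n": "pairwise-complete sample size",
    "r": "Pearson r (NaN when not computable)",
    "p": "two-tailed p-value, uncorrected by design",
    "significant": "p < 0.05, uncorrected",
    "computable": "false when n < 3 or a variable had zero variance",
    "p_bh": "optional BH-adjusted p over computable rows (not used for significance)"
  },
  "brain_behavior_ordered.csv": {
    "region_id": "row label; columns are stratum/measure pairs ordered by UPGMA clustering",
    "<stratum>/<measure>": "Pearson r value"
  },
  "volumes.csv": {
    "subject_id": "unique subject identifier",
    "<region_id>": "absolute regional volume (mm^3), strictly positive"
  },
  "design.csv": {
    "subject_id": "unique subject identifier",
    "sex": "M | F",
    "group": "treated | control"
  },
  "behavior.csv": {
    "subject_id": "unique subject identifier",
    "<measure>": "behavioral value; blank when the measure was not collected"
  },
  "manifest.json": {
    "command": "argv of the run",
    "inputs": "mapping input path -> sha256 of file content",
    "config": "resolved option values",
    "seed": "random seed when randomness was involved",
    "package_version": "structcov version",
    "timestamp": "UTC ISO-8601 run time (informational; not part of output determinism)"
  }
}
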