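# Property-range panels. Bounds are closed on finite ends; "-inf"/"inf" open a
# side. "drugs95" carries the ranges observed for 95% of known drugs as given
# in the descriptor definitions; "drugs95_results" swaps in the variant bounds
# quoted alongside the per-descriptor discussion (logK_HSA upper 1.5, logBB
# upper 1.2, metab 1-8). star_members lists the descriptors counted toward
# #stars.
#
# The MW/logP/HBA/HBD/NRB rows use the QikProp-recommended ranges; the Caco-2
# band is an assumption (the printed guidance is a qualitative low/high
# scale) — see docs/methods.md.
drugs95:
  ranges:
    S_mol:      {lower: 300.0, upper: 1000.0}
    S_mol_hfob: {lower: 0.0, upper: 750.0}
    V_mol:      {lower: 500.0, upper: 2000.0}
    logS_wat:   {lower: -6.0, upper: 0.5}
    logK_HSA:   {lower: -1.5, upper: 1.2}
    logBB:      {lower: -3.0, upper: 1.0}
    caco2:      {lower: 25.0, upper: inf, note: "assumed band; printed guidance: <5 low, >100 high"}
    mdck:       {lower: 25.0, upper: 500.0, note: "printed guidance: <25 poor, >500 great"}
    ind_coh:    {lower: 0.0, upper: 0.05}
    glob:       {lower: 0.75, upper: 0.95}
    polrz:      {lower: 13.0, upper: 70.0}
    logHERG:    {lower: -5.0, upper: inf, note: "concern < -5"}
    logKp:      {lower: -8.0, upper: -1.0}
    metab:      {lower: 0.0, upper: 15.0}
    MW:         {lower: 130.0, upper: 725.0}
    logP:       {lower: -2.0, upper: 6.5}
    HBA:        {lower: 2.0, upper: 20.0}
    HBD:        {lower: 0.0, upper: 6.0}
    NRB:        {lower: 0.0, upper: 15.0}
  star_members:
    [S_mol, S_mol_hfob, V_mol, logS_wat, logK_HSA, logBB, caco2, mdck,
     ind_coh, glob, polrz, logHERG, logKp, metab, MW, logP, HBA, HBD, NRB]

drugs95_results:
  ranges:
    S_mol:      {lower: 300.0, upper: 1000.0}
    S_mol_hfob: {lower: 0.0, upper: 750.0}
    V_mol:      {lower: 500.0, upper: 2000.0}
    logS_wat:   {lower: -6.0, upper: 0.5}
    logK_HSA:   {lower: -1.5, upper: 1.5}
    logBB:      {lower: -3.0, upper: 1.2}
    caco2:      {lower: 25.0, upper: inf}
    mdck:       {lower: 25.0, upper: 500.0}
    ind_coh:    {lower: 0.0, upper: 0.05}
    glob:       {lower: 0.75, upper: 0.95}
    polrz:      {lower: 13.0, upper: 70.0}
    logHERG:    {lower: -5.0, upper: inf}
    logKp:      {lower: -8.0, upper: -1.0}
    metab:      {lower: 1.0, upper: 8.0}
    MW:         {lower: 130.0, upper: 725.0}
    logP:       {lower: -2.0, upper: 6.5}
    HBA:        {lower: 2.0, upper: 20.0}
    HBD:        {lower: 0.0, upper: 6.0}
    NRB:        {lower: 0.0, upper: 15.0}
  star_members:
    [S_mol, S_mol_hfob, V_mol, logS_wat, logK_HSA, logBB, caco2, mdck,
     ind_coh, glob, polrz, logHERG, logKp, metab, MW, logP, HBA, HBD, NRB]
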