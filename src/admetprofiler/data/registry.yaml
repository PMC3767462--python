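# Canonical descriptor registry: name -> units, description, external aliases.
# The alias lists cover the QikProp export dialect and common CSV headers;
# edit freely — alias resolution is case-insensitive and many-to-one.
MW:
  units: Da
  description: molecular weight
  aliases: ["mol MW", "mol.MW", "mol_MW", "MolWt", "weight"]
logP:
  units: ""
  description: log10 octan-1-ol/water partition coefficient
  aliases: ["QPlogPo/w", "QPlogPow", "LogP", "clogP"]
HBA:
  units: count
  description: hydrogen-bond acceptor count
  aliases: ["accptHB", "acceptHB", "n_HBA"]
HBD:
  units: count
  description: hydrogen-bond donor count (heavy-atom convention)
  aliases: ["donorHB", "n_HBD"]
NRB:
  units: count
  description: rotatable-bond count (amide C-N excluded)
  aliases: ["#rotor", "rotor", "n_rot"]
S_mol:
  units: "A^2"
  description: total solvent-accessible surface area, 1.4 A probe
  aliases: ["SASA", "Smol", "total SASA"]
S_mol_hfob:
  units: "A^2"
  description: hydrophobic portion of the solvent-accessible surface
  aliases: ["FOSA", "Smol,hfob", "hydrophobic SASA"]
V_mol:
  units: "A^3"
  description: volume enclosed by the solvent-accessible surface
  aliases: ["volume", "Vmol", "SAV"]
logS_wat:
  units: "log mol/L"
  description: log10 aqueous solubility
  aliases: ["QPlogS", "logS", "LogSwat"]
ci_logS_wat:
  units: "log mol/L"
  description: conformation-independent log10 aqueous solubility
  aliases: ["CIQPlogS", "CI logS"]
logK_HSA:
  units: ""
  description: log10 binding constant to human serum albumin
  aliases: ["QPlogKhsa", "logKhsa"]
logBB:
  units: ""
  description: log10 blood/brain partition coefficient
  aliases: ["QPlogBB", "log B/B", "logB/B"]
caco2:
  units: "nm/s"
  description: apparent Caco-2 cell permeability (Boehringer-Ingelheim scale)
  aliases: ["QPPCaco", "BIP_Caco-2", "Caco-2", "PCaco"]
mdck:
  units: "nm/s"
  description: apparent MDCK cell permeability
  aliases: ["QPPMDCK", "MDCK", "PMDCK"]
ind_coh:
  units: ""
  description: "cohesion-in-solids index: HBA*HBD/S_mol"
  aliases: ["Ind_coh", "Indcoh"]
glob:
  units: ""
  description: globularity, 4*pi*r^2/S_mol with r the equal-volume-sphere radius
  aliases: ["Glob", "globularity"]
polrz:
  units: "A^3"
  description: predicted polarizability
  aliases: ["QPpolrz", "polarizability"]
logHERG:
  units: ""
  description: predicted log IC50 for HERG K+ channel blockage
  aliases: ["QPlogHERG", "HERG"]
logKp:
  units: ""
  description: log10 skin permeability coefficient (cm/h)
  aliases: ["QPlogKp", "logK_p", "Kp"]
metab:
  units: count
  description: predicted number of likely metabolic reactions
  aliases: ["#metab", "n_metab"]
stars:
  units: count
  description: number of descriptors outside the 95%-of-drugs ranges
  aliases: ["#stars", "n_stars"]
cns:
  units: ""
  description: predicted CNS activity, integer scale -2 (inactive) .. +2 (active)
  aliases: ["CNS", "CNS activity"]
percent_HOA:
  units: "%"
  description: predicted percent human oral absorption (0-100)
  aliases: ["PercentHumanOralAbsorption", "%HOA", "percent HOA"]
hoa_class:
  units: ""
  description: "qualitative oral absorption: 1=low, 2=medium, 3=high"
  aliases: ["HumanOralAbsorption", "HOA class"]
jm:
  units: "ug/cm^2/h"
  description: maximum transdermal transport rate Jm = Kp*MW*S_wat
  aliases: ["Jm", "J_m"]
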