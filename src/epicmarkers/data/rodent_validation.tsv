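species	Abcb9-2	Agxt-10	Catsper3-5	Dhcr24-7	Ivd-8	Nadsyn1-4	Rras-4	Smo-9	Trpv4-8	Wls-7
Octodontomys_gliroides	65-55	65-55	65-55	65-55	65-55	65-55	fail	65-55	65-55	65-55
Atherurus_macrourus	65-55	65-60	65-55	65-55	65-55	65-55	fail	65-55	65-55	65-55
Proechimys_guairae	65-55	65-55	fail	65-55	65-55	65-55	fail	fail	fail	65-55
Myocastor_coypus	65-55	fail	fail	65-55	fail	65-55	fail	fail	fail	fail
Hydrochoerus_hydrochaeris	65-55	65-55	65-55	65-55	65-55	fail	65-55	65-55	65-55	65-55
Cynomys_ludovicianus	65-55	fail	65-55	65-60	65-55	65-55	65-55	65-55	65-55	65-55
Sciurus_vulgaris	65-55	fail	65-55	65-55	65-55	65-55	65-55	65-55	65-55	65-55
Glis_glis	fail	fail	65-55	65-55	65-55	65-55	fail	65-55	fail	65-55
Apodemus_flavicollis	65-55	65-55	fail	65-55	65-55	65-55	65-55	65-55	65-55	65-55
Microtus_duodecimcostatus	65-55	65-55	65-55	65-55	65-55	65-55	65-55	65-55	fail	65-55
Microtus_lusitanicus	65-50	65-50	65-50	65-55	65-55	65-50	65-50	65-55	fail	65-55
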