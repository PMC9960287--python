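# Families and orders of viruses that infect exclusively bacteria or archaea.
# One name per line; an explicit "family:" or "order:" prefix restricts the
# rank at which the name matches, otherwise it matches at either rank.
# Representative list compiled for this toolkit from current ICTV taxonomy;
# maintained here as plain text so it can be audited and extended.
family:Myoviridae
family:Siphoviridae
family:Podoviridae
family:Ackermannviridae
family:Autographiviridae
family:Herelleviridae
family:Demerecviridae
family:Drexlerviridae
family:Straboviridae
family:Peduoviridae
family:Schitoviridae
family:Zobellviridae
family:Kyanoviridae
family:Mesyanzhinovviridae
family:Casjensviridae
family:Microviridae
family:Inoviridae
family:Plectroviridae
family:Fiersviridae
family:Leviviridae
family:Cystoviridae
family:Tectiviridae
family:Corticoviridae
family:Plasmaviridae
family:Sphaerolipoviridae
family:Fuselloviridae
family:Lipothrixviridae
family:Rudiviridae
family:Bicaudaviridae
family:Ampullaviridae
family:Globuloviridae
family:Guttaviridae
family:Turriviridae
family:Portogloboviridae
family:Tristromaviridae
order:Caudovirales
order:Crassvirales
order:Ligamenvirales
order:Tubulavirales
order:Petitvirales
order:Norzivirales
order:Timlovirales
order:Belfryvirales
order:Halopanivirales
order:Vinavirales
order:Kirjokansivirales
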