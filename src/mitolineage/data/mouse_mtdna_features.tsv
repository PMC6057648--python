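# Mouse mitochondrial genome feature map, 1-based inclusive coordinates.
# Transcribed from the public NC_005089.1 (C57BL/6J; numbering-compatible with
# AY172335) GenBank annotation. ETAS/CSB sub-region bounds inside the control
# region are approximate literature intervals; the NCR bounds themselves
# (15423-16299) are exact.
name	class	start	end	strand	complex
mt-Tf	tRNA	1	68	heavy	none
mt-Rnr1	rRNA	70	1024	heavy	none
mt-Tv	tRNA	1025	1093	heavy	none
mt-Rnr2	rRNA	1094	2675	heavy	none
mt-Tl1	tRNA	2676	2750	heavy	none
mt-Nd1	protein	2751	3707	heavy	COMI
mt-Ti	tRNA	3706	3774	heavy	none
mt-Tq	tRNA	3772	3842	light	none
mt-Tm	tRNA	3845	3913	heavy	none
mt-Nd2	protein	3914	4951	heavy	COMI
mt-Tw	tRNA	4950	5016	heavy	none
mt-Ta	tRNA	5018	5086	light	none
mt-Tn	tRNA	5089	5159	light	none
mt-Tc	tRNA	5192	5258	light	none
mt-Ty	tRNA	5259	5326	light	none
mt-Co1	protein	5328	6872	heavy	COMIV
mt-Ts1	tRNA	6870	6938	light	none
mt-Td	tRNA	6942	7011	heavy	none
mt-Co2	protein	7013	7696	heavy	COMIV
mt-Tk	tRNA	7700	7764	heavy	none
mt-Atp8	protein	7766	7969	heavy	COMV
mt-Atp6	protein	7927	8607	heavy	COMV
mt-Co3	protein	8607	9390	heavy	COMIV
mt-Tg	tRNA	9391	9458	heavy	none
mt-Nd3	protein	9459	9806	heavy	COMI
mt-Tr	tRNA	9808	9875	heavy	none
mt-Nd4l	protein	9877	10173	heavy	COMI
mt-Nd4	protein	10167	11544	heavy	COMI
mt-Th	tRNA	11546	11614	heavy	none
mt-Ts2	tRNA	11615	11673	heavy	none
mt-Tl2	tRNA	11674	11742	heavy	none
mt-Nd5	protein	11742	13565	heavy	COMI
mt-Nd6	protein	13552	14070	light	COMI
mt-Te	tRNA	14071	14139	light	none
mt-Cytb	protein	14145	15288	heavy	COMIII
mt-Tt	tRNA	15289	15355	heavy	none
mt-Tp	tRNA	15356	15422	light	none
NCR	NCR	15423	16299	heavy	none
ETAS1	ETAS	15424	15479	heavy	none
ETAS2	ETAS	15508	15564	heavy	none
CSB1	CSB	16035	16058	heavy	none
CSB2	CSB	16089	16104	heavy	none
CSB3	CSB	16114	16133	heavy	none
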