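gene_id	female	male	symbol	arabidopsis_homolog	stages	function
sunup.05G0006810	EXP	NO	CpAGL6	AT2G45650	FS2-3	Flowing time
sunup.04G0000360	EXP	NO	CpHEC2	AT3G50330	FS1/FS2-3/FS4	Gynoecium development
sunup.03G0006060	EXP	NO	CpSUPL	AT3G23130	FS1/FS2-3/FS4	Carpel development
sunup.01G0026370	EXP	NO	CpAGL11	AT4G09960	FS1/FS2-3/FS4	Carpel and ovule development
sunup.01G0022430	EXP	NO	CpSVPL	AT4G24540	FS1	Flowing
sunup.02G0012880	EXP	NO	CpTGA9	AT1G08320	FS2-3/FS4	Flower development
sunup.01G0000330	EXP	NO	CpCYC	AT1G67260	FS2-3/FS4	Longitudinal elongation of petioles, rosette leaves and inflorescent stems
sunup.04G0001590	EXP	NO	CpDOF5.7L	AT5G65590	FS4	Guard cell differentiation
sunup.04G0003750	EXP	NO	CpHBI1L	AT2G18300	FS4	Cell elongation and proliferation
sunup.03G0023770	EXP	NO	CpZAT11	AT2G42410	FS4	Flower growth and development
sunup.05G0010320	EXP	NO	CpMYC2	AT4G00870	FS4	Jasmonate-mediated growth
sunup.08G0004940	EXP	NO	CpATH51	AT5G03790	FS2-3/FS4	Organ proportions
sunup.02G0001210	EXP	NO	CpbHLH30	AT1G68810	FS4	Leaf development
sunup.02G0008550	EXP	NO	CpWIP6	AT1G13290	FS4	Shoot and root development
sunup.02G0002680	EXP	NO	CpPRE5L	AT3G28857	FS2-3/FS4	Cell elongation and plant development
sunup.09G0005320	EXP	NO	CpWOX1	AT3G18010	FS2-3/FS4	Leaf blade outgrowth and floral organ development
sunup.03G0015290	EXP	NO	CpSCL32	AT3G49950	FS4	Regulate growth and flowering
sunup.04G0013610	EXP	NO	CpBLH4	AT4G36870	FS2-3/FS4	Ovule morphogenesis
sunup.03G0020730	NO	EXP	CpMUTE	AT3G06120	MS2-3	Stomatal development
sunup.06G0008830	NO	EXP	CpAMS	AT2G16910	MS2-3	Tapetal cell development
sunup.01G0006170	NO	EXP	CpBZIP43L	AT5G38800	MS1/MS4	NA
sunup.08G0003710	NO	EXP	CpNAC90L	AT3G44350	MS4	NA
sunup.02G0022760	NO	EXP	CpDIV	AT5G58900	MS1/MS4	Vascular development
sunup.06G0024960	NO	EXP	CpMYB5	AT3G13540	MS1/MS4	Seed coat and endosperm layers formation
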