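>syn_cas1_like synthetic Cas-family protein (randomly generated stand-in)
DNSNSLLNADTLSADSTGGAINGTENTTKGAESLLNENSAWFEIMKGGETEDRNVLVTGGNGPYWHDSPS
KTDLKHPLVSGQAGKNFVAIEQDDMESRKGLAVKCTQTESERLNEGPTGLISVGRQDQLLRSVLPVDKTL
GSIGPGCRVLGTNPRQPKLIGAANEKLPMNLFGPQHDLLLSNVENGFSADQRFLPKPGSEGQGRSQTNLN
QVKAIFLCSNGVTETTTKHDALAHRVKGSNGFDWYQFLTSMIMLDITF
>syn_cas2_like synthetic Cas-family protein (randomly generated stand-in)
DSSDMVRGYSYLTGVMKPVPHIVRPYYGPRYTSALLLLQRGLTKSEAQFKSWPAFLLQDLVIQTTAGQSL
VANSPGMFDGDSWPGGTLKVIKPVEFIYEIANRADMADIDYFQKWADTVKAMLSTVQKEIDFASIPYLSR
SLTTSDPPGRCHLPTSVGGDQIGRQNIKDRHTTLYLADVVSYIGTRAAGTGNYLTLEDLSSDIAQAEANE
MMSKTHVSLQPEPTGKGELIFGPYIFLNFIEGDCYYAEYGKSNACLFTIGTEMSCNTSFSNKISVFDHNH
CMAK
>syn_cas3_like synthetic Cas-family protein (randomly generated stand-in)
PADSPGITVLLQAIRASPQKAVRNFRVTRTELTEINFKRNTLEIDGKGSDVIISLLMILKQTAQAPHPFE
AGSFESLIIEDALREKLPFKQQFTLKTNSPKAPLSAGAYEVGVPAEENRLSRCVDVDADVKGPCDASILP
DFDWELALAGQALANLASVVAKYLRIDRLDQPDDPMTFLIGNTDCGTQGNEIGTLAQRVGVEETLADLQA
LGQLAMPCDLFHVAGFGSIRKEKQSGELEIQAAPRGDVVALDLNNASQATQCLMSTDLEDVKSANVPRDL
TDHIIICSPNIDDAPKANLT
>syn_cas9_like synthetic Cas-family protein (randomly generated stand-in)
TRIGRSAGNVEEQYDRGLAAGDDGAFLIVPASHKASAIQSFYVEMNMPDSIGRIVAPTPKKIQSRSPCFV
CTQETSVNSEDICSSQTRGIQARTDLGLNRGPAVYPSIAGEPRKNPGNTARIKYYATLCGRNKWHLLNKS
DFKEGKETICTLLADYNVTEIEVASIGVGLQYQCYEGECDMQQYTVRHGILCRQIQTHVSLGGAFEDLVV
LREVESSVIANSNLGPYHSVSQMGMPFELDIERQGSSQIDRKMKVKLACKMTAPALGALDDMDDIDRLSI
SIQMEFTLTNVETPNIWGKSL
>syn_cas10_like synthetic Cas-family protein (randomly generated stand-in)
LDDASVYAFGMNKPYYLVGLSRGLAIMLAAKRTDLVCGSAKSWNTLDQDMGPADSKEAFEDSYPAQQSLS
RAKSELGAGAVVVCIGAWWKGSNAVAGLVVTLFPPAFDTYVKLKLSRPDAVLTGKWPMYRSSKKAQQAET
AEHKVCIDLKTKYLLSFIKIPQWKQCQNLQFGAGGSCSEVPVLKIFDDGELSPRTVVALDKLFEGRIFNC
LADVAPCKGAKPITIAVTPFYKMELRPGDRTPNLILFTPKD
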