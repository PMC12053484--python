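>IHF_54
TQLVDVREYINSSIVEDSSPIYPVELLNHFQNNVIGWAQWIAIITMGTRYHKGNRWEMQITMLNRATIAMYTWWDGFREL
PFDNTFNKTMTSQKYCDLMMREEAFVELAW
>MCP
RASECQYKIVMESGKWMYKDSPIHTIRNHIGGLGQMQDGIVYGCSQVPGKTMYQHMLCAYFPLVAQAHNCRTEDAARWTC
FDKMNKSMMFWHHLLNQEPTPHVPIEATWNYAGCPSLVYIFWSKCCIMWLCIGNYHQPIQFNIKCCSHGGAQFAMDNLDS
LGHEKKQVFIGIYLPDCNRDCGYDEHENFHAAPWWFHYWDVVCGKELHKMGKIHRLFGCGNNTCSGPKIWCVPDEVRQEA
CLNQYCFYLKMDGTSCCDTISPHAEENMMTMLRDLKPSICAEEVGAGHEQCMMSLNDTADTVEYIWQIAGVGGIEHACQW
PNCWFISWTMPIGMWNMLHKPPVGIPEWCPSKGVKYIWTCYTQSPAGWHVDDVRSIEDQT
>portal
AKLHSSFQTPQLRYHWSKEVRKARWVYYKTHTHKQTIQLKMKAIVRQYTLVVQYLVLRHEHYRGPQDDSPQSPRSVQPCV
HNKNMDSGDVETSLCCIALMRTSWQTPSLYFGIVGNNMKCKRAFLAFHQECTNMHRKCIYVGEPGEMWWKACEGVKANAA
DHEIQVHTRECSICQQSIFSSLPDCRTGKHDPNSRWNQNLWQDKECLERMCDQVSEVAAYRKTGIAWERYSRRHENTTTH
KTFIRFDVIDGCWNLWCEAGIDSCPIHHPHDPCPLNTKDYRHREGSLRGCAGTLTDGDRIQRFGFSNMFLPKMGCVMLDG
TQKEMPNVHVNIKGAAYPPNLLSQPIARWPKQNPYIPSEEHPIHFGEEFWIAQDHETFPHWQLRRACHMGLNYHSSREWT
DVDFACVCYDVPRQERQEGVYYPRGKVMAWYIRMGMQLRGYVWQVRIFFI
>TerL
VKIEYFWRGGGDPYDHLGFMAVPMCALWQPDPKYPDFNTWSNEMNRFMYLDCKDHSETKVVPACGPSSSEIYMNCKQWRN
DYLVEQPKSSECWAYKAATIGISGPFIVHDATTTAVHRIFSRKEPYGWKNHAQDSMFPMYPYVMPKYKPKMRGHHFKDHN
HLAPNVHHIRFCENYLIHATRHPPVHIPHSVIQMQMMFNEMFMWALRDNIHGSPWHQLAHALKHMWRFKQQPPRSTQPPN
DTFQHASCCQFMESGGFIFTYANIRPTQPQAGYGQHLHNTAKYLDVAWEGYRGMNRHRCSGRHEEMGCLKHWYQYKSCME
YDLHYMNNHVRLFNYIQVIDIRLTSCIIRDRVKRQHKRNMMVNMYSRMTVFHVMVLGDMMCRWCEWTHMQCSAWTAYIDA
ANSWVKYVWWFFYDNQIIWN
>primase
QAQKPYMLCWPYSIVDCGHHNLARNDQSNFQRAWYLKPGPNCMFRRRGIAFGRREPAWVWVHAPWISADKFSEIDEFECD
QNANSRCENDLWRTTPINEDFTISHYPVIEFMFEVHFVSGECHMRTRIYLCMGMDTPPTRTRHTCLAVDQINWFIHTEKW
IWQWKMQTYALTEGEKEKSRFVNAFMTAALRLPHCSTIQPLSPKIEDQYEVFWNCSAFHPESTCDKSGGIASAHQMEERV
TSELKCSKWWDPTHWDDQNTTTFCFRSCYYEFDHISIAWWIPDYDRPYMTTELYKRNHMCWFFQADVYEIDSDNVAYYPM
RLGCQHTISPLQWNQGADSPDEECHYDNWLMYGSDFHWGK
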